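"""Per-reaction two-group differential-abundance testing.

Each reaction is tested for a difference in mean relative abundance between
the two phenotype groups with Welch's t-statistic under a permutation null
(exact enumeration of all distinct label assignments when their number is
small, Monte-Carlo otherwise) or, optionally, the Welch t-distribution.
Two-sided p-values are converted to signed Z-scores

    z = sign(mean_G1 - mean_G2) * Phi^{-1}(1 - p/2)

which become the edge weights of the metabolic network: positive when the
reaction is more abundant in group G1, negative when more abundant in G2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .netio import AbundanceMatrix, GroupDesign

__all__ = [
    "TestConfig",
    "ReactionStat",
    "relative_abundance",
    "reaction_pvalue",
    "p_to_z",
    "compute_reaction_stats",
]

# relative slack when counting permutations at least as extreme as the
# observed statistic, so float noise never un-ties an exact tie
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class TestConfig:
    """How per-reaction p-values are computed.

    engine
        ``"permutation"`` (default) or ``"tdist"`` (Welch t-distribution with
        Satterthwaite degrees of freedom).
    b
        Monte-Carlo permutation count B; p = (r+1)/(B+1).
    exhaustive
        ``"auto"`` enumerates all distinct group-label assignments whenever
        there are at most ``exhaustive_cap`` of them (252 for 5 vs 5 samples);
        ``True``/``False`` force the choice.
    """

    engine: str = "permutation"
    b: int = 1000
    exhaustive: bool | str = "auto"
    exhaustive_cap: int = 10_000
    seed: int | None = None

    def __post_init__(self):
        if self.engine not in ("permutation", "tdist"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.b < 1:
            raise ValueError("b must be >= 1")

    def use_exhaustive(self, n1: int, n2: int) -> bool:
        if self.engine != "permutation":
            return False
        if self.exhaustive == "auto":
            return math.comb(n1 + n2, n1) <= self.exhaustive_cap
        if self.exhaustive and math.comb(n1 + n2, n1) > self.exhaustive_cap:
            raise ValueError(
                f"exhaustive enumeration of C({n1 + n2},{n1}) assignments "
                f"exceeds cap {self.exhaustive_cap}"
            )
        return bool(self.exhaustive)


@dataclass(frozen=True)
class ReactionStat:
    """Differential-abundance result for one reaction.

    ``p`` is the two-sided p-value in (0, 1]; ``z`` the signed Z-score with
    sign +1 when the reaction is more abundant in G1, -1 when more abundant
    in G2, 0 when the group means are equal (then z = 0).
    """

    reaction_id: str
    mean_g1: float
    mean_g2: float
    p: float
    z: float

    @property
    def sign(self) -> int:
        if self.mean_g1 > self.mean_g2:
            return 1
        if self.mean_g1 < self.mean_g2:
            return -1
        return 0


def relative_abundance(m: AbundanceMatrix) -> AbundanceMatrix:
    """Column-normalize counts so each sample sums to 1."""
    totals = m.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {m.sample_ids[zero[0]]!r} has zero total count"
        )
    return AbundanceMatrix(m.reaction_ids, m.sample_ids, m.counts / totals)


def _all_split_masks(n: int, n1: int) -> np.ndarray:
    """Boolean (n, S) matrix of every distinct size-n1 group-1 assignment.

    Column 0 is the identity assignment {0, ..., n1-1}.
    """
    combos = list(combinations(range(n), n1))
    masks = np.zeros((n, len(combos)), dtype=bool)
    for j, c in enumerate(combos):
        masks[list(c), j] = True
    return masks


def _welch_t(X: np.ndarray, masks: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Welch t for every row of X (R, n) under every assignment column of masks.

    Zero pooled standard error: t = 0 when the means are equal, +/-inf
    otherwise.  Returns (R, S).
    """
    M = masks.astype(float)
    s1 = X @ M
    s2 = X.sum(axis=1, keepdims=True) - s1
    q1 = (X * X) @ M
    q2 = (X * X).sum(axis=1, keepdims=True) - q1
    m1 = s1 / n1
    m2 = s2 / n2
    v1 = np.maximum(q1 - n1 * m1 * m1, 0.0) / (n1 - 1)
    v2 = np.maximum(q2 - n2 * m2 * m2, 0.0) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    # rounding can leave tiny diffs with exactly-zero variance; treat a
    # relative difference below 1e-12 as equal means
    scale = np.maximum(np.abs(m1), np.abs(m2)) + 1e-300
    equal = np.abs(diff) <= 1e-12 * scale
    with np.errstate(invalid="ignore"):
        t = np.where(se2 > 0, t, np.where(equal, 0.0, np.sign(diff) * np.inf))
    return t


def _extreme_threshold(t_obs: np.ndarray) -> np.ndarray:
    a = np.abs(t_obs)
    return a * (1 - _TIE_RTOL) - 1e-12


def _welch_df(X: np.ndarray, i1: np.ndarray, i2: np.ndarray) -> np.ndarray:
    x, y = X[:, i1], X[:, i2]
    n1, n2 = len(i1), len(i2)
    v1 = x.var(axis=1, ddof=1) / n1
    v2 = y.var(axis=1, ddof=1) / n2
    num = (v1 + v2) ** 2
    den = v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = num / den
    return np.where(den > 0, df, 1.0)


def pvalues_matrix(
    X: np.ndarray,
    i1: np.ndarray,
    i2: np.ndarray,
    cfg: TestConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two-sided p-values for every row of X, groups given by column indices."""
    n1, n2 = len(i1), len(i2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    Xs = X[:, np.concatenate([i1, i2])]
    n = n1 + n2
    obs_mask = np.zeros((n, 1), dtype=bool)
    obs_mask[:n1, 0] = True
    t_obs = _welch_t(Xs, obs_mask, n1, n2)[:, 0]

    if cfg.engine == "tdist":
        df = _welch_df(Xs, np.arange(n1), np.arange(n1, n))
        with np.errstate(invalid="ignore"):
            p = 2 * sps.t.sf(np.abs(t_obs), df)
        p = np.where(np.isinf(t_obs), 0.0, p)
        p = np.where(t_obs == 0, 1.0, p)
        return np.clip(p, 1e-300, 1.0)

    if cfg.use_exhaustive(n1, n2):
        masks = _all_split_masks(n, n1)
        T = _welch_t(Xs, masks, n1, n2)
        r = (np.abs(T) >= _extreme_threshold(t_obs)[:, None]).sum(axis=1)
        return r / masks.shape[1]

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    masks = np.zeros((n, cfg.b), dtype=bool)
    for j in range(cfg.b):
        masks[rng.permutation(n)[:n1], j] = True
    T = _welch_t(Xs, masks, n1, n2)
    r = (np.abs(T) >= _extreme_threshold(t_obs)[:, None]).sum(axis=1)
    return (r + 1) / (cfg.b + 1)


def reaction_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    cfg: TestConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided p-value for one reaction (values in G1 vs values in G2)."""
    cfg = cfg or TestConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    X = np.concatenate([x, y])[None, :]
    i1 = np.arange(x.size)
    i2 = np.arange(x.size, x.size + y.size)
    return float(pvalues_matrix(X, i1, i2, cfg, rng)[0])


def p_to_z(p: float, mean_g1: float, mean_g2: float) -> float:
    """Signed Z-score from a two-sided p-value and the group means."""
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if mean_g1 == mean_g2:
        return 0.0
    sign = 1.0 if mean_g1 > mean_g2 else -1.0
    return float(sign * sps.norm.isf(p / 2))


def compute_reaction_stats(
    m: AbundanceMatrix,
    d: GroupDesign,
    cfg: TestConfig | None = None,
    *,
    normalize: bool = True,
    rng: np.random.Generator | None = None,
) -> list[ReactionStat]:
    """One ReactionStat per matrix row; deterministic given the seed.

    Counts are converted to per-sample relative abundances first unless
    ``normalize=False``.  All-zero (or otherwise constant, equal-mean) rows
    get p = 1 and z = 0.  P-values are clamped below at the permutation
    resolution so the Z conversion stays finite.
    """
    cfg = cfg or TestConfig()
    mm = relative_abundance(m) if normalize else m
    i1, i2 = d.indices(mm.sample_ids)
    p = pvalues_matrix(mm.counts, i1, i2, cfg, rng)
    floor = 1 / (cfg.b + 1) if cfg.engine == "permutation" else 1e-300
    p = np.clip(p, floor, 1.0)
    m1 = mm.counts[:, i1].mean(axis=1)
    m2 = mm.counts[:, i2].mean(axis=1)
    return [
        ReactionStat(rid, float(a), float(b), float(pv), p_to_z(float(pv), a, b))
        for rid, a, b, pv in zip(mm.reaction_ids, m1, m2, p)
    ]
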
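"""Subnetwork significance and the iterative discovery loop.

Two complementary permutation p-values are attached to every candidate
subnetwork found by the greedy search:

* ``p_abund`` — permute the sample-group labels (columns of the abundance
  matrix), recompute the member reactions' p-values and Z-scores under each
  permutation, and compare the permuted aggregate scores with the observed
  one.  This asks: is this particular set of reactions differentially
  abundant?  It ignores network topology.
* ``p_struct`` — permute the edge weights across the whole (current) network,
  rerun the greedy search at the observed subnetwork size k, and compare the
  null maxima with the observed score.  This asks: how easily does the
  topology produce an equally good subnetwork from reshuffled weights?  In a
  densely connected network random high-weight edges cluster by chance, so a
  small p_abund alone can be misleading; p_struct guards against that
  selection bias.

Both use the (r+1)/(B+1) estimator, so p ∈ [1/(B+1), 1].  A subnetwork is
significant when p_abund ≤ α_abund AND p_struct ≤ α_struct (defaults
0.05/0.05).  ``discover`` repeatedly extracts the best subnetwork, tests it,
removes significant members from the network, and also runs the mirrored
(negated-weight) search so that subnetworks enriched in either group are
found; results are ranked by p_abund.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .diffabund import (
    ReactionStat,
    TestConfig,
    _all_split_masks,
    _extreme_threshold,
    _welch_df,
    _welch_t,
    compute_reaction_stats,
    relative_abundance,
)
from .netio import AbundanceMatrix, GroupDesign, MetabolicNetwork
from .search import (
    GraphIndex,
    Subnetwork,
    batch_fixed_k_scores,
    batch_free_scores,
    greedy_search,
)

__all__ = [
    "SignificanceConfig",
    "SubnetworkResult",
    "p_abund",
    "p_struct",
    "discover",
]

_TOL = 1e-9


@dataclass(frozen=True)
class SignificanceConfig:
    """Permutation counts, thresholds, and the inner test engine."""

    b_abund: int = 1000
    b_struct: int = 1000
    test: TestConfig = field(default_factory=TestConfig)
    alpha_abund: float = 0.05
    alpha_struct: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.b_abund < 1 or self.b_struct < 1:
            raise ValueError("permutation counts must be >= 1")
        for a in (self.alpha_abund, self.alpha_struct):
            if not (0 < a < 1):
                raise ValueError(f"alpha must be in (0, 1), got {a}")


@dataclass(frozen=True)
class SubnetworkResult:
    """A significant subnetwork with both p-values and its rank."""

    subnetwork: Subnetwork
    p_abund: float
    p_struct: float
    enriched_in: str
    rank: int | None = None

    def is_significant(self, cfg: SignificanceConfig) -> bool:
        return self.p_abund <= cfg.alpha_abund and self.p_struct <= cfg.alpha_struct


def _member_scores_all_splits(X: np.ndarray, n1: int, n2: int):
    """Aggregate subnetwork score under every distinct label assignment.

    X holds the member reactions' relative abundances (k rows).  For each of
    the S = C(n, n1) assignments the member p-values are exact-enumeration
    permutation p-values (ranks of |t| within the full assignment set), which
    makes observed and permuted scores exchangeable by construction.
    Returns (scores over assignments, index of the identity assignment).
    """
    n = n1 + n2
    masks = _all_split_masks(n, n1)
    S = masks.shape[1]
    T = _welch_t(X, masks, n1, n2)  # (k, S)
    A = np.abs(T)
    # p[i, a] = fraction of assignments b with |T[i,b]| >= |T[i,a]|
    thresh = A * (1 - 1e-9) - 1e-12
    p = (A[:, :, None] >= thresh[:, None, :]).sum(axis=0 + 1) / S  # sum over b
    M = masks.astype(float)
    m1 = (X @ M) / n1
    m2 = (X.sum(axis=1, keepdims=True) - X @ M) / n2
    sign = np.sign(m1 - m2)
    z = sign * sps.norm.isf(np.clip(p, 1e-300, 1.0) / 2)
    return z.sum(axis=0), 0  # identity assignment is column 0


def p_abund(
    s: Subnetwork,
    m: AbundanceMatrix,
    d: GroupDesign,
    cfg: SignificanceConfig | None = None,
    *,
    direction: int = 1,
    rng: np.random.Generator | None = None,
) -> float:
    """Sample-label permutation p-value for a subnetwork's aggregate score.

    ``direction=-1`` evaluates the mirrored (G2-enriched) search, i.e. the
    null asks for permuted scores at least as *negative* as observed.
    """
    cfg = cfg or SignificanceConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rel = relative_abundance(m)
    rows = rel.row_indices(s.edges)  # KeyError -> hard error per contract
    i1, i2 = d.indices(rel.sample_ids)
    n1, n2 = len(i1), len(i2)
    X = rel.counts[np.ix_(rows, np.concatenate([i1, i2]))]

    inner = cfg.test
    if inner.engine == "permutation" and inner.use_exhaustive(n1, n2):
        scores, obs_col = _member_scores_all_splits(X, n1, n2)
        obs = direction * scores[obs_col]
        draws = rng.integers(scores.shape[0], size=cfg.b_abund)
        null = direction * scores[draws]
    else:
        obs = direction * _score_given_assignment(X, np.arange(n1 + n2), n1, inner, rng)
        null = np.empty(cfg.b_abund)
        for b in range(cfg.b_abund):
            perm = rng.permutation(n1 + n2)
            null[b] = direction * _score_given_assignment(X, perm, n1, inner, rng)
    r = int((null >= obs - _TOL).sum())
    return (r + 1) / (cfg.b_abund + 1)


def _score_given_assignment(
    X: np.ndarray, order: np.ndarray, n1: int, inner: TestConfig,
    rng: np.random.Generator,
) -> float:
    """Member-summed signed Z for one column assignment (first n1 = G1)."""
    Xp = X[:, order]
    n = X.shape[1]
    n2 = n - n1
    mask = np.zeros((n, 1), dtype=bool)
    mask[:n1, 0] = True
    t_obs = _welch_t(Xp, mask, n1, n2)[:, 0]
    if inner.engine == "tdist":
        df = _welch_df(Xp, np.arange(n1), np.arange(n1, n))
        with np.errstate(invalid="ignore"):
            p = 2 * sps.t.sf(np.abs(t_obs), df)
        p = np.where(np.isinf(t_obs), 1e-300, p)
        p = np.where(t_obs == 0, 1.0, p)
    else:
        masks = np.zeros((n, inner.b), dtype=bool)
        for j in range(inner.b):
            masks[rng.permutation(n)[:n1], j] = True
        T = _welch_t(Xp, masks, n1, n2)
        r = (np.abs(T) >= _extreme_threshold(t_obs)[:, None]).sum(axis=1)
        p = (r + 1) / (inner.b + 1)
    p = np.clip(p, 1e-300, 1.0)
    m1 = Xp[:, :n1].mean(axis=1)
    m2 = Xp[:, n1:].mean(axis=1)
    z = np.sign(m1 - m2) * sps.norm.isf(p / 2)
    return float(z.sum())


def p_struct(
    s: Subnetwork,
    net: MetabolicNetwork | GraphIndex,
    w,
    *,
    mode: str = "subgraph",
    cfg: SignificanceConfig | None = None,
    size_cap: int = 30,
    seeds: str = "all_edges",
    chain_extend: str = "both",
    null_size: str = "matched",
    rng: np.random.Generator | None = None,
) -> float:
    """Edge-weight permutation p-value with a topology-aware null.

    Weights are permuted uniformly across all edges of the (current) global
    network; each permutation is searched greedily with the same mode and
    caps as the observed search.  ``null_size="matched"`` (default) fixes the
    null search at the observed size k = s.k — the classical size-matched
    null; searches that cannot reach k edges contribute -inf (never
    extreme).  ``null_size="free"`` reruns the free-size search on each
    permutation instead, so the null maximizes over sizes exactly as the
    observed statistic did; when the observed subnetwork came from a
    free-size search this is the exchangeable construction (the size-matched
    null under-covers the observed max-over-sizes selection and is then
    anticonservative).
    """
    cfg = cfg or SignificanceConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if null_size not in ("matched", "free"):
        raise ValueError(f"null_size must be 'matched' or 'free', got {null_size!r}")
    idx = net if isinstance(net, GraphIndex) else GraphIndex(net)
    k = s.k
    if k < 1:
        raise ValueError("subnetwork is empty")
    if k > size_cap:
        raise ValueError(f"subnetwork size {k} exceeds size_cap {size_cap}")
    wv = np.asarray(w, dtype=float) if isinstance(w, np.ndarray) else idx.weights_vector(w)
    obs = s.score
    n_e = len(wv)
    perms = np.empty((cfg.b_struct, n_e))
    for b in range(cfg.b_struct):
        perms[b] = wv[rng.permutation(n_e)]
    if mode == "subgraph":
        if null_size == "matched":
            null = batch_fixed_k_scores(idx, perms, k, seeds=seeds)
        else:
            null = batch_free_scores(idx, perms, size_cap, seeds=seeds)
    else:
        null = np.empty(cfg.b_struct)
        kf = k if null_size == "matched" else None
        for b in range(cfg.b_struct):
            sb = greedy_search(
                idx, perms[b], mode=mode, k_fixed=kf,
                size_cap=size_cap, seeds=seeds, chain_extend=chain_extend,
            )
            null[b] = sb.score if sb is not None else -np.inf
    r = int((null >= obs - _TOL).sum())
    return (r + 1) / (cfg.b_struct + 1)


def discover(
    net: MetabolicNetwork,
    m: AbundanceMatrix,
    d: GroupDesign,
    cfg: SignificanceConfig | None = None,
    *,
    mode: str = "subgraph",
    size_cap: int = 30,
    seeds: str = "all_edges",
    chain_extend: str = "both",
    null_size: str = "free",
    stats: Sequence[ReactionStat] | None = None,
) -> tuple[list[SubnetworkResult], list[ReactionStat]]:
    """Find all significant subnetworks by iterative extraction.

    Loop: run the greedy free-size search on the remaining network (first
    with the observed weights for G1-enriched sets, then mirrored with
    negated weights for G2-enriched sets); compute p_abund and, if it passes,
    p_struct; when significant, record the result, remove its member edges
    from the network, and restart.  Stops when neither direction yields a
    significant subnetwork.  Each acceptance removes at least one edge, so
    termination is guaranteed.  Returns (ranked significant results,
    per-reaction statistics).

    Because the discovery search is free-size, p_struct defaults to the
    selection-matched free-size null (``null_size="free"``), which keeps the
    false-discovery behavior of the joint rule near its nominal level; the
    classical size-matched null is available with ``null_size="matched"``.
    """
    cfg = cfg or SignificanceConfig()
    rng = np.random.default_rng(cfg.seed)
    if stats is None:
        stats = compute_reaction_stats(m, d, cfg.test, rng=rng)
    zmap = {st.reaction_id: st.z for st in stats}

    current = net
    results: list[SubnetworkResult] = []
    while current.n_edges > 0:
        idx = GraphIndex(current)
        wv = idx.weights_vector(zmap)
        accepted = False
        for direction in (1, -1):
            cand = greedy_search(
                idx, direction * wv, mode=mode, size_cap=size_cap,
                seeds=seeds, chain_extend=chain_extend,
            )
            if cand is None or cand.score <= 0:
                continue
            pa = p_abund(cand, m, d, cfg, direction=direction, rng=rng)
            if pa > cfg.alpha_abund:
                continue
            ps = p_struct(
                cand, idx, direction * wv, mode=mode, cfg=cfg,
                size_cap=size_cap, seeds=seeds, chain_extend=chain_extend,
                null_size=null_size, rng=rng,
            )
            if ps > cfg.alpha_struct:
                continue
            raw_score = float(direction * cand.score)
            results.append(
                SubnetworkResult(
                    subnetwork=Subnetwork(edges=cand.edges, score=raw_score),
                    p_abund=pa,
                    p_struct=ps,
                    enriched_in=d.g1 if raw_score > 0 else d.g2,
                )
            )
            current = current.without_edges(cand.edges)
            accepted = True
            break
        if not accepted:
            break

    order = sorted(
        range(len(results)),
        key=lambda i: (
            results[i].p_abund,
            results[i].p_struct,
            -abs(results[i].subnetwork.score),
        ),
    )
    ranked = [
        SubnetworkResult(
            subnetwork=results[i].subnetwork,
            p_abund=results[i].p_abund,
            p_struct=results[i].p_struct,
            enriched_in=results[i].enriched_in,
            rank=rank,
        )
        for rank, i in enumerate(order, start=1)
    ]
    ranked.sort(key=lambda r: r.rank)
    return ranked, list(stats)
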
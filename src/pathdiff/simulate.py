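"""Planted-signal simulation and method benchmarking.

The generator emulates a two-group metagenomic comparison: a random connected
metabolic network with an embedded simple path ("planted chain"), and a
Gaussian abundance matrix in which every reaction i has its own mean μ_i
(log-uniform over [10, 1000] by default) and standard deviation σ_i = RSD·μ_i
with RSD = 0.2.  Non-planted reactions draw all samples from the same
distribution; planted reactions are enriched in group 1 by shifting the mean
so that the *expected* two-sample t-statistic sits at the two-sided critical
boundary of a chosen significance level (0.05 or 0.01).  Defaults: 5 subjects
per group, chain length 5, draws truncated at zero.

For benchmarking, reactions are also assigned to contiguous synthetic
"pathway" blocks (a stand-in for curated pathway definitions), with the
planted chain straddling a block boundary — exactly the situation where
aggregate per-pathway testing dilutes the signal.  ``evaluate_roc`` turns any
per-reaction ranking into an ROC curve and AUC against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .diffabund import TestConfig, compute_reaction_stats
from .netio import AbundanceMatrix, GroupDesign, MetabolicNetwork, ReactionEdge
from .significance import SubnetworkResult

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_network",
    "effect_shift",
    "simulate_abundance",
    "simulate_dataset",
    "evaluate_roc",
    "RocResult",
    "baseline_methods",
    "reaction_ranking_from_results",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-signal generator.

    ``effect_alpha`` is the target two-sample significance of the planted
    shift; ``planted_length`` the number of reactions in the enriched chain
    (0 = null data).  ``n_compounds`` defaults to ``n_reactions``, roughly
    the compound:reaction ratio of the global metabolic network.
    ``block_size`` controls the synthetic pathway blocks used by the
    pathway-aggregate baseline; with ``straddle_blocks`` the planted chain is
    placed across a block boundary.
    """

    n_per_group: int = 5
    rsd: float = 0.2
    planted_length: int = 5
    effect_alpha: float = 0.01
    n_reactions: int = 500
    n_compounds: int | None = None
    baseline_means: Sequence[float] | None = None
    mean_range: tuple[float, float] = (10.0, 1000.0)
    block_size: int = 20
    straddle_blocks: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.rsd <= 0:
            raise ValueError("rsd must be positive")
        if not (0 <= self.planted_length <= self.n_reactions):
            raise ValueError("planted_length must be in [0, n_reactions]")
        if not (0 < self.effect_alpha < 1):
            raise ValueError("effect_alpha must be in (0, 1)")

    @property
    def resolved_n_compounds(self) -> int:
        c = self.n_compounds if self.n_compounds is not None else self.n_reactions
        return max(c, self.planted_length + 1)


@dataclass(frozen=True)
class SimulatedDataset:
    """Generator output: network, counts, design, ground truth, blocks."""

    network: MetabolicNetwork
    matrix: AbundanceMatrix
    design: GroupDesign
    planted: frozenset[str]
    blocks: Mapping[str, int] = field(default_factory=dict)


def _reaction_id(i: int) -> str:
    return f"R{i + 1:04d}"


def simulate_network(
    n_compounds: int,
    n_reactions: int,
    embed_path_length: int,
    seed: int | None = None,
    *,
    planted_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MetabolicNetwork, list[str]]:
    """A connected random network with a designated embedded simple path.

    The path's edges are oriented along it (so it is always a valid chain);
    every edge is reversible with probability 1/2.  Returns the network and
    the path's reaction ids in path order.
    """
    if embed_path_length > n_reactions:
        raise ValueError("embed_path_length exceeds n_reactions")
    if n_compounds < embed_path_length + 1:
        raise ValueError("need at least embed_path_length + 1 compounds")
    if n_reactions < n_compounds - 1:
        raise ValueError(
            f"{n_reactions} reactions cannot connect {n_compounds} compounds"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    L = embed_path_length
    if planted_ids is None:
        planted_ids = [_reaction_id(i) for i in range(L)]
    elif len(planted_ids) != L:
        raise ValueError("planted_ids length must equal embed_path_length")
    other_ids = iter(
        rid for i in range(n_reactions)
        if (rid := _reaction_id(i)) not in set(planted_ids)
    )

    compounds = [f"C{i + 1:04d}" for i in range(n_compounds)]
    # Random-attachment tree, with the path compounds inserted at uniformly
    # random times (relative order kept) so their degrees are exchangeable
    # with every other compound's: inserting them first would make them
    # high-degree hubs and confound planted status with topology.
    path_slots = set(
        int(x) for x in rng.choice(n_compounds, size=L + 1, replace=False)
    )
    nonpath = [compounds[j] for j in rng.permutation(np.arange(L + 1, n_compounds))]
    path_iter = iter(compounds[: L + 1])
    np_iter = iter(nonpath)
    edges: list[ReactionEdge] = []
    inserted: list[str] = []
    planted_iter = iter(planted_ids)
    for slot in range(n_compounds):
        if slot in path_slots:
            c = next(path_iter)
            on_path = c != compounds[0]
        else:
            c = next(np_iter)
            on_path = False
        if on_path:
            # path edge, oriented along the path so the chain stays valid
            prev = compounds[compounds.index(c) - 1]
            edges.append(
                ReactionEdge(next(planted_iter), prev, c, bool(rng.random() < 0.5))
            )
        elif inserted:
            anchor = inserted[int(rng.integers(len(inserted)))]
            u, v = (anchor, c) if rng.random() < 0.5 else (c, anchor)
            edges.append(ReactionEdge(next(other_ids), u, v, bool(rng.random() < 0.5)))
        inserted.append(c)
    # remaining reactions: random compound pairs (no self-loops)
    while len(edges) < n_reactions:
        u, v = rng.choice(n_compounds, size=2, replace=False)
        edges.append(
            ReactionEdge(
                next(other_ids), compounds[int(u)], compounds[int(v)],
                bool(rng.random() < 0.5),
            )
        )
    return MetabolicNetwork(edges), list(planted_ids)


def effect_shift(
    mu: float, sigma: float, n_per_group: int, effect_alpha: float
) -> float:
    """Mean for the enriched group placing E[t] at the significance boundary.

    mu' = mu + t_crit * sigma * sqrt(2 / n), with t_crit the two-sided
    critical value of Student's t at ``effect_alpha`` with 2n - 2 degrees of
    freedom.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t_crit = sps.t.ppf(1 - effect_alpha / 2, 2 * n_per_group - 2)
    return mu + t_crit * sigma * np.sqrt(2.0 / n_per_group)


def simulate_abundance(
    network: MetabolicNetwork,
    planted: Sequence[str],
    cfg: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Gaussian abundance matrix over the network's reactions.

    Group 2 always draws from N(μ_i, σ_i²); planted reactions draw group 1
    from the shifted N(μ_i', σ_i²).  Draws are truncated at zero (counts are
    non-negative).  Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    reaction_ids = sorted(network.edge_ids)
    planted_set = frozenset(planted)
    missing = planted_set - set(reaction_ids)
    if missing:
        raise ValueError(f"planted reactions not in network: {sorted(missing)}")
    n = cfg.n_per_group
    sample_ids = [f"G1S{i + 1}" for i in range(n)] + [f"G2S{i + 1}" for i in range(n)]
    design = GroupDesign({s: s[:2] for s in sample_ids}, "G1", "G2")

    R = len(reaction_ids)
    if cfg.baseline_means is not None:
        mus = np.asarray(cfg.baseline_means, dtype=float)
        if mus.shape != (R,):
            raise ValueError(f"baseline_means must have length {R}")
    else:
        lo, hi = np.log10(cfg.mean_range[0]), np.log10(cfg.mean_range[1])
        mus = 10 ** rng.uniform(lo, hi, size=R)
    sigmas = cfg.rsd * mus
    counts = rng.normal(mus[:, None], sigmas[:, None], size=(R, 2 * n))
    if planted_set:
        pidx = np.array([i for i, r in enumerate(reaction_ids) if r in planted_set])
        shifted = np.array(
            [effect_shift(mus[i], sigmas[i], n, cfg.effect_alpha) for i in pidx]
        )
        counts[pidx, :n] = rng.normal(
            shifted[:, None], sigmas[pidx, None], size=(len(pidx), n)
        )
    counts = np.clip(counts, 0.0, None)
    matrix = AbundanceMatrix(reaction_ids, sample_ids, counts)
    blocks = {r: i // cfg.block_size for i, r in enumerate(reaction_ids)}
    return SimulatedDataset(network, matrix, design, planted_set, blocks)


def _planted_indices(cfg: SimulationConfig) -> list[int]:
    """Row indices of the planted chain, straddling a block boundary."""
    L = cfg.planted_length
    if L == 0:
        return []
    if cfg.straddle_blocks and cfg.block_size < cfg.n_reactions and L > 1:
        start = max(0, cfg.block_size - (L + 1) // 2)
        if start + L > cfg.n_reactions:
            start = cfg.n_reactions - L
    else:
        start = 0
    return list(range(start, start + L))


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """One full synthetic study: network + matrix + design + truth."""
    rng = np.random.default_rng(cfg.seed)
    planted_ids = [_reaction_id(i) for i in _planted_indices(cfg)]
    network, planted = simulate_network(
        cfg.resolved_n_compounds,
        cfg.n_reactions,
        cfg.planted_length,
        planted_ids=planted_ids or None,
        rng=rng,
    )
    if cfg.planted_length == 0:
        planted = []
    return simulate_abundance(network, planted, cfg, rng=rng)


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def evaluate_roc(
    scores: Mapping[str, float], planted: Sequence[str] | frozenset[str]
) -> RocResult:
    """ROC curve and AUC for a per-reaction ranking (higher = more planted).

    AUC is the Mann-Whitney statistic with mid-ranks for ties.
    """
    truth_set = set(planted)
    if not truth_set:
        raise ValueError("empty truth set")
    rids = sorted(scores)
    if not truth_set <= set(rids):
        raise ValueError("scores do not cover the truth set")
    y = np.array([r in truth_set for r in rids])
    x = np.array([scores[r] for r in rids], dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0:
        raise ValueError("no negative reactions")
    ranks = sps.rankdata(x)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    # curve: sweep thresholds from high to low
    order = np.argsort(-x, kind="mergesort")
    tp = np.concatenate([[0], np.cumsum(y[order])])
    fp = np.concatenate([[0], np.cumsum(~y[order])])
    return RocResult(fpr=fp / n0, tpr=tp / n1, auc=float(auc))


def baseline_methods(
    dataset: SimulatedDataset,
    cfg: TestConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, float]]:
    """Per-reaction ranking scores for the two comparison baselines.

    ``per_reaction``: 1 - p from the per-reaction test (single-reaction
    differential abundance).  ``pathway_blocks``: aggregate the counts of
    each synthetic pathway block, test the block totals, and give every
    member reaction its block's 1 - p (the predefined-container approach).
    """
    cfg = cfg or TestConfig()
    m, d = dataset.matrix, dataset.design
    stats = compute_reaction_stats(m, d, cfg, rng=rng)
    per_reaction = {st.reaction_id: 1 - st.p for st in stats}

    blocks = dataset.blocks
    missing = [r for r in m.reaction_ids if r not in blocks]
    if missing:
        raise ValueError(f"reactions without a pathway block: {missing[:5]}")
    block_ids = sorted(set(blocks.values()))
    bpos = {b: i for i, b in enumerate(block_ids)}
    agg = np.zeros((len(block_ids), len(m.sample_ids)))
    for i, r in enumerate(m.reaction_ids):
        agg[bpos[blocks[r]]] += m.counts[i]
    bm = AbundanceMatrix([f"block{b}" for b in block_ids], m.sample_ids, agg)
    bstats = compute_reaction_stats(bm, d, cfg, rng=rng)
    bp = {block_ids[i]: st.p for i, st in enumerate(bstats)}
    pathway = {r: 1 - bp[blocks[r]] for r in m.reaction_ids}
    return {"per_reaction": per_reaction, "pathway_blocks": pathway}


def reaction_ranking_from_results(
    results: Sequence[SubnetworkResult],
    stats,
) -> dict[str, float]:
    """Subnetwork-aware per-reaction ranking.

    Reactions inside a significant subnetwork score 1 - p_abund of their
    subnetwork; all others fall back to 1 - their own reaction p-value.
    """
    scores = {st.reaction_id: 1 - st.p for st in stats}
    for res in results:
        for rid in res.subnetwork.edges:
            scores[rid] = max(scores.get(rid, 0.0), 1 - res.p_abund)
    return scores
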
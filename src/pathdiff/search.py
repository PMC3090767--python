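"""Greedy maximum-weight connected-subnetwork search.

Edges of the metabolic network carry signed Z-scores as weights; the score of
a subnetwork is the sum of its members' weights.  Two edges are adjacent when
they share a compound endpoint (a line-graph view), and a subnetwork must be
connected under this relation.  Two search modes exist:

* ``subgraph`` — arbitrary connected edge sets;
* ``chain`` — simple compound paths whose successive reactions are
  direction-compatible (irreversible edges traversed source→target only).

The greedy heuristic seeds a growth at every edge (or every positive edge),
repeatedly adds the highest-weight frontier edge, records the cumulative
score after every addition, and returns the best-scoring prefix over all
seeds; with ``k_fixed`` the candidate is the prefix of exactly k edges.
Finding the true optimum is NP-hard; an exhaustive ``brute_force_search`` is
provided as a test oracle for small graphs.  All tie-breaks are
deterministic: weight ties resolve to the lexicographically smallest reaction
id, candidate ties to the higher score, then the smaller size, then the
lexicographically smallest sorted id list.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .netio import MetabolicNetwork, ReactionEdge

__all__ = [
    "Subnetwork",
    "GraphIndex",
    "edge_adjacency",
    "greedy_search",
    "brute_force_search",
    "chain_feasible",
    "batch_fixed_k_scores",
]

_SCORE_ATOL = 1e-9


@dataclass(frozen=True)
class Subnetwork:
    """A connected set of reaction edges with its aggregate score.

    ``edges`` are in order of greedy addition; ``score`` is the sum of the
    member weights; ``k`` the number of member reactions.
    """

    edges: tuple[str, ...]
    score: float

    @property
    def k(self) -> int:
        return len(self.edges)


class GraphIndex:
    """Array view of a network for fast search.

    Edges are indexed in lexicographic reaction-id order so that numpy
    argmax (first maximum) realizes the lexicographic tie-break.
    """

    def __init__(self, net: MetabolicNetwork):
        self.net = net
        self.edge_ids = sorted(net.edge_ids)
        self.pos = {r: i for i, r in enumerate(self.edge_ids)}
        edges = [net.edge(r) for r in self.edge_ids]
        compounds = sorted(net.compounds)
        cpos = {c: i for i, c in enumerate(compounds)}
        self.u = np.array([cpos[e.source] for e in edges], dtype=int)
        self.v = np.array([cpos[e.target] for e in edges], dtype=int)
        self.reversible = np.array([e.reversible for e in edges], dtype=bool)
        self.self_loop = self.u == self.v
        n_e = len(edges)
        # incident edge lists per compound
        self.incident: list[list[int]] = [[] for _ in compounds]
        for i in range(n_e):
            self.incident[self.u[i]].append(i)
            if self.v[i] != self.u[i]:
                self.incident[self.v[i]].append(i)
        # line-graph adjacency (shared endpoint, self excluded)
        adj = np.zeros((n_e, n_e), dtype=bool)
        for inc in self.incident:
            for i in inc:
                for j in inc:
                    if i != j:
                        adj[i, j] = True
        self.adj = adj

    def weights_vector(self, w: Mapping[str, float]) -> np.ndarray:
        wv = np.zeros(len(self.edge_ids))
        for i, rid in enumerate(self.edge_ids):
            if rid in w:
                x = float(w[rid])
                if not np.isfinite(x):
                    raise ValueError(f"non-finite weight for reaction {rid!r}")
                wv[i] = x
        return wv


def edge_adjacency(net: MetabolicNetwork) -> dict[str, set[str]]:
    """For every reaction, the set of other reactions sharing a compound."""
    idx = GraphIndex(net)
    return {
        rid: {idx.edge_ids[j] for j in np.flatnonzero(idx.adj[i])}
        for i, rid in enumerate(idx.edge_ids)
    }


def _better(
    cand: tuple[float, int, tuple[str, ...]],
    best: tuple[float, int, tuple[str, ...]] | None,
) -> bool:
    """Candidate comparison: higher score, then smaller k, then lexicographic."""
    if best is None:
        return True
    ds = cand[0] - best[0]
    if abs(ds) > _SCORE_ATOL:
        return ds > 0
    if cand[1] != best[1]:
        return cand[1] < best[1]
    return tuple(sorted(cand[2])) < tuple(sorted(best[2]))


def _grow_subgraph(idx: GraphIndex, wv: np.ndarray, seed: int, cap: int):
    """Greedy growth from one seed; returns (order, cumulative scores)."""
    n_e = len(wv)
    in_set = np.zeros(n_e, dtype=bool)
    in_set[seed] = True
    avail = idx.adj[seed].copy()
    order = [seed]
    cum = [wv[seed]]
    while len(order) < cap:
        masked = np.where(avail, wv, -np.inf)
        j = int(np.argmax(masked))
        if masked[j] == -np.inf:
            break
        order.append(j)
        cum.append(cum[-1] + wv[j])
        in_set[j] = True
        avail |= idx.adj[j]
        avail &= ~in_set
    return order, cum


def _chain_extensions(idx: GraphIndex, head: int, tail: int, used_edges, used_comp):
    """Direction-compatible extensions of the current path at either end.

    Yields (edge, end, new_compound); ``end`` is 't' (append after tail) or
    'h' (prepend before head).  An irreversible edge u→v may only leave u and
    enter v; reversible edges go either way.  Self-loops never extend chains
    and the compound path stays simple.
    """
    for i in idx.incident[tail]:
        if i in used_edges or idx.self_loop[i]:
            continue
        if idx.u[i] == tail:
            nc = idx.v[i]
        elif idx.reversible[i]:
            nc = idx.u[i]
        else:
            continue
        if nc not in used_comp:
            yield i, "t", nc
    for i in idx.incident[head]:
        if i in used_edges or idx.self_loop[i]:
            continue
        if idx.v[i] == head:
            nc = idx.u[i]
        elif idx.reversible[i]:
            nc = idx.v[i]
        else:
            continue
        if nc not in used_comp:
            yield i, "h", nc


def _grow_chain(idx: GraphIndex, wv: np.ndarray, seed: int, cap: int, extend: str):
    """Greedy chain growth from one seed edge (both orientations if reversible)."""
    orientations = [(idx.u[seed], idx.v[seed])]
    if idx.reversible[seed] and extend == "one":
        orientations.append((idx.v[seed], idx.u[seed]))
    best_order, best_cum = None, None
    for head0, tail0 in orientations:
        head, tail = int(head0), int(tail0)
        used_edges = {seed}
        used_comp = {head, tail}
        order = [seed]
        cum = [wv[seed]]
        while len(order) < cap:
            cands = list(_chain_extensions(idx, head, tail, used_edges, used_comp))
            if extend == "one":
                cands = [c for c in cands if c[1] == "t"]
            if not cands:
                break
            # weight desc, then lexicographic edge id, then tail before head
            cands.sort(key=lambda c: (-wv[c[0]], idx.edge_ids[c[0]], c[1] != "t"))
            j, end, nc = cands[0]
            order.append(j)
            cum.append(cum[-1] + wv[j])
            used_edges.add(j)
            used_comp.add(nc)
            if end == "t":
                tail = nc
            else:
                head = nc
        if best_order is None or cum[-1] > best_cum[-1]:
            best_order, best_cum = order, cum
    return best_order, best_cum


def greedy_search(
    net: MetabolicNetwork | GraphIndex,
    w: Mapping[str, float] | np.ndarray,
    *,
    mode: str = "subgraph",
    k_fixed: int | None = None,
    size_cap: int = 30,
    seeds: str = "all_edges",
    chain_extend: str = "both",
) -> Subnetwork | None:
    """Best greedy subnetwork, or None when no candidate exists.

    Free-size mode returns the best-scoring growth prefix over all seeds;
    with ``k_fixed`` only prefixes of exactly k edges are candidates.
    Deterministic for fixed inputs.
    """
    if mode not in ("subgraph", "chain"):
        raise ValueError(f"unknown mode {mode!r}")
    if seeds not in ("all_edges", "positive_edges"):
        raise ValueError(f"unknown seed rule {seeds!r}")
    if chain_extend not in ("both", "one"):
        raise ValueError(f"chain_extend must be 'both' or 'one'")
    if size_cap < 1:
        raise ValueError("size_cap must be >= 1")
    if k_fixed is not None and k_fixed > size_cap:
        raise ValueError(f"k_fixed={k_fixed} exceeds size_cap={size_cap}")

    idx = net if isinstance(net, GraphIndex) else GraphIndex(net)
    wv = np.asarray(w, dtype=float) if isinstance(w, np.ndarray) else idx.weights_vector(w)
    if wv.shape != (len(idx.edge_ids),):
        raise ValueError("weight vector length does not match network")

    if len(idx.edge_ids) == 0:
        return None
    seed_idx = range(len(idx.edge_ids)) if seeds == "all_edges" else np.flatnonzero(wv > 0)

    best: tuple[float, int, tuple[str, ...]] | None = None
    for s in seed_idx:
        if mode == "chain":
            if idx.self_loop[s]:
                continue
            order, cum = _grow_chain(idx, wv, int(s), size_cap, chain_extend)
        else:
            order, cum = _grow_subgraph(idx, wv, int(s), size_cap)
        if k_fixed is None:
            j = int(np.argmax(cum))  # best prefix; ties -> smaller k
            cand = (
                float(cum[j]),
                j + 1,
                tuple(idx.edge_ids[i] for i in order[: j + 1]),
            )
        else:
            if len(order) < k_fixed:
                continue
            cand = (
                float(cum[k_fixed - 1]),
                k_fixed,
                tuple(idx.edge_ids[i] for i in order[:k_fixed]),
            )
        if _better(cand, best):
            best = cand
    if best is None:
        return None
    return Subnetwork(edges=best[2], score=best[0])


_BRUTE_GUARD = 16


def brute_force_search(
    net: MetabolicNetwork | GraphIndex,
    w: Mapping[str, float] | np.ndarray,
    k: int,
    *,
    mode: str = "subgraph",
) -> Subnetwork | None:
    """Exact maximum-weight connected edge set (or chain) of size k.

    Exhaustive-enumeration oracle; refuses networks over 16 edges.
    """
    idx = net if isinstance(net, GraphIndex) else GraphIndex(net)
    n_e = len(idx.edge_ids)
    if n_e > _BRUTE_GUARD:
        raise ValueError(f"brute force limited to {_BRUTE_GUARD} edges, got {n_e}")
    if k < 1:
        raise ValueError("k must be >= 1")
    wv = np.asarray(w, dtype=float) if isinstance(w, np.ndarray) else idx.weights_vector(w)

    best: tuple[float, int, tuple[str, ...]] | None = None
    if mode == "subgraph":
        for combo in combinations(range(n_e), k):
            if not _connected(idx, combo):
                continue
            ids = tuple(idx.edge_ids[i] for i in combo)
            cand = (float(wv[list(combo)].sum()), k, ids)
            if _better(cand, best):
                best = cand
    elif mode == "chain":
        for path in _all_chains(idx, k):
            ids = tuple(idx.edge_ids[i] for i in path)
            cand = (float(wv[list(path)].sum()), k, ids)
            if _better(cand, best):
                best = cand
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if best is None:
        return None
    return Subnetwork(edges=best[2], score=best[0])


def _connected(idx: GraphIndex, combo: Sequence[int]) -> bool:
    members = set(combo)
    stack = [combo[0]]
    seen = {combo[0]}
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(idx.adj[i]):
            if j in members and j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return len(seen) == len(members)


def _all_chains(idx: GraphIndex, k: int):
    """All simple direction-compatible compound paths of exactly k edges."""
    n_e = len(idx.edge_ids)

    def extend(path, comps, tail):
        if len(path) == k:
            yield tuple(path)
            return
        for i in idx.incident[tail]:
            if i in path or idx.self_loop[i]:
                continue
            if idx.u[i] == tail:
                nc = int(idx.v[i])
            elif idx.reversible[i]:
                nc = int(idx.u[i])
            else:
                continue
            if nc in comps:
                continue
            yield from extend(path + [i], comps | {nc}, nc)

    for s in range(n_e):
        if idx.self_loop[s]:
            continue
        starts = [(int(idx.u[s]), int(idx.v[s]))]
        if idx.reversible[s]:
            starts.append((int(idx.v[s]), int(idx.u[s])))
        for h, t in starts:
            yield from extend([s], {h, t}, t)


def chain_feasible(net: MetabolicNetwork | GraphIndex, edge_ids: Iterable[str]) -> bool:
    """Whether an edge set forms a simple, direction-compatible compound path."""
    idx = net if isinstance(net, GraphIndex) else GraphIndex(net)
    members = [idx.pos[r] for r in edge_ids]
    if not members:
        return False
    k = len(members)
    if k == 1:
        return not idx.self_loop[members[0]]
    if any(idx.self_loop[i] for i in members):
        return False
    # walk from every possible start orientation of every member edge
    mset = set(members)

    def walk(path, comps, tail):
        if len(path) == k:
            return True
        for i in idx.incident[tail]:
            if i not in mset or i in path:
                continue
            if idx.u[i] == tail:
                nc = int(idx.v[i])
            elif idx.reversible[i]:
                nc = int(idx.u[i])
            else:
                continue
            if nc in comps:
                continue
            if walk(path + [i], comps | {nc}, nc):
                return True
        return False

    for s in members:
        starts = [(int(idx.u[s]), int(idx.v[s]))]
        if idx.reversible[s]:
            starts.append((int(idx.v[s]), int(idx.u[s])))
        for h, t in starts:
            if walk([s], {h, t}, t):
                return True
    return False


def batch_fixed_k_scores(
    idx: GraphIndex,
    weight_rows: np.ndarray,
    k: int,
    *,
    seeds: str = "all_edges",
    chunk: int = 32,
) -> np.ndarray:
    """Fixed-k subgraph-mode greedy score for every row of ``weight_rows``.

    Vectorized across seeds and weight rows; identical growth and
    tie-breaking to ``greedy_search(..., mode="subgraph", k_fixed=k)``.
    Rows where no seed can grow to k edges score ``-inf``.  Used to build
    the weight-permutation (p_struct) null distribution efficiently.
    """
    W = np.asarray(weight_rows, dtype=float)
    n_b, n_e = W.shape
    if n_e != len(idx.edge_ids):
        raise ValueError("weight rows do not match network size")
    out = np.empty(n_b)
    for lo in range(0, n_b, chunk):
        out[lo : lo + chunk] = _batch_chunk(idx, W[lo : lo + chunk], k, seeds)
    return out


def batch_free_scores(
    idx: GraphIndex,
    weight_rows: np.ndarray,
    size_cap: int = 30,
    *,
    seeds: str = "all_edges",
    chunk: int = 32,
) -> np.ndarray:
    """Free-size subgraph-mode greedy score (best prefix) per weight row.

    The batched counterpart of ``greedy_search(..., mode="subgraph")`` with
    no fixed size: the score of the best prefix over all seeds.
    """
    W = np.asarray(weight_rows, dtype=float)
    n_b, n_e = W.shape
    if n_e != len(idx.edge_ids):
        raise ValueError("weight rows do not match network size")
    out = np.empty(n_b)
    for lo in range(0, n_b, chunk):
        out[lo : lo + chunk] = _batch_chunk(
            idx, W[lo : lo + chunk], None, seeds, size_cap=size_cap
        )
    return out


def _batch_chunk(
    idx: GraphIndex, W: np.ndarray, k: int | None, seeds: str, size_cap: int = 30
) -> np.ndarray:
    n_b, n_e = W.shape
    adj = idx.adj
    if seeds != "all_edges":
        # positive seeds differ per row; fall back to scalar greedy per row
        out = np.empty(n_b)
        for b in range(n_b):
            s = greedy_search(idx, W[b], mode="subgraph", k_fixed=k,
                              size_cap=max(k or 0, size_cap), seeds=seeds)
            out[b] = s.score if s is not None else -np.inf
        return out
    seed_cols = np.arange(n_e)
    n_s = n_e
    n_steps = k if k is not None else min(size_cap, n_e)
    rows_w = np.repeat(W, n_s, axis=0)               # (n_b*n_s, n_e)
    rr = np.arange(n_b * n_s)
    scores = rows_w[rr, np.tile(seed_cols, n_b)].copy()
    best = scores.copy()                             # running best prefix
    in_set = np.zeros((n_b * n_s, n_e), dtype=bool)
    in_set[rr, np.tile(seed_cols, n_b)] = True
    avail = np.tile(adj[seed_cols], (n_b, 1))
    alive = np.ones(n_b * n_s, dtype=bool)
    for _step in range(1, n_steps):
        masked = np.where(avail & ~in_set, rows_w, -np.inf)
        j = masked.argmax(axis=1)
        val = masked[rr, j]
        alive = alive & np.isfinite(val)
        scores = np.where(alive, scores + np.where(alive, rows_w[rr, j], 0.0), scores)
        best = np.maximum(best, np.where(alive, scores, -np.inf))
        upd = np.flatnonzero(alive)
        in_set[upd, j[upd]] = True
        avail[upd] |= adj[j[upd]]
    if k is not None:
        per_row = np.where(alive, scores, -np.inf)
    else:
        per_row = best
    return per_row.reshape(n_b, n_s).max(axis=1)
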
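"""Data model and on-disk formats for metabolic networks and abundance data.

The global metabolic network is a graph whose nodes are metabolic compounds
(substrates) and whose edges are molecular reactions; an edge may be
unidirectional or bidirectional depending on whether the reaction is
reversible.  Abundances are raw mapped-read counts per reaction per sample.

On-disk formats (all plain text, tab- or whitespace-separated):

* network edge list — 4 columns ``reaction_id source target reversible``
  with ``reversible`` in ``{0, 1}``; lines starting with ``#`` are comments.
* abundance matrix — TSV, header row of sample ids, first column reaction ids.
* group table — TSV with two columns ``sample_id  group``.
* BLAST tabular hits (outfmt-6 style) plus a gene→reaction mapping table.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReactionEdge",
    "MetabolicNetwork",
    "AbundanceMatrix",
    "GroupDesign",
    "read_network",
    "write_network",
    "read_abundance",
    "write_abundance",
    "read_groups",
    "write_groups",
    "counts_from_hits",
    "reconcile",
    "write_report",
    "subnetwork_dot",
]


@dataclass(frozen=True)
class ReactionEdge:
    """A molecular reaction connecting two compounds.

    ``reversible`` edges may be traversed in either direction when chains are
    assembled; irreversible edges only from ``source`` to ``target``.
    Self-loops (source == target) are legal but never extend chains.
    """

    reaction_id: str
    source: str
    target: str
    reversible: bool = False


class MetabolicNetwork:
    """Compounds as nodes, reactions as (possibly reversible) edges.

    Reaction identifiers are unique across edges; parallel edges between the
    same compound pair are permitted as long as their reaction ids differ.
    The graph may be disconnected.
    """

    def __init__(
        self,
        edges: Iterable[ReactionEdge],
        compounds: Iterable[str] | None = None,
    ):
        self.edges: list[ReactionEdge] = list(edges)
        seen: dict[str, int] = {}
        for i, e in enumerate(self.edges):
            if e.reaction_id in seen:
                raise ValueError(
                    f"duplicate reaction id {e.reaction_id!r} "
                    f"(edges {seen[e.reaction_id]} and {i})"
                )
            seen[e.reaction_id] = i
        self._index = seen
        self.compounds: set[str] = set(compounds) if compounds else set()
        for e in self.edges:
            self.compounds.add(e.source)
            self.compounds.add(e.target)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_ids(self) -> list[str]:
        return [e.reaction_id for e in self.edges]

    def edge(self, reaction_id: str) -> ReactionEdge:
        return self.edges[self._index[reaction_id]]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self._index

    def without_edges(self, reaction_ids: Iterable[str]) -> "MetabolicNetwork":
        """A new network with the given reactions removed (compounds kept)."""
        drop = set(reaction_ids)
        return MetabolicNetwork(
            [e for e in self.edges if e.reaction_id not in drop],
            compounds=self.compounds,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return self.edges == other.edges and self.compounds == other.compounds

    def __repr__(self) -> str:
        return (
            f"MetabolicNetwork({len(self.compounds)} compounds, "
            f"{self.n_edges} reactions)"
        )


def read_network(path: str | os.PathLike) -> MetabolicNetwork:
    """Read an edge-list file: ``reaction_id source target reversible``."""
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(parts)}"
                )
            rid, src, tgt, rev = parts
            if rev not in ("0", "1"):
                raise ValueError(
                    f"{path}: line {lineno}: reversible flag must be 0 or 1, "
                    f"got {rev!r}"
                )
            edges.append(ReactionEdge(rid, src, tgt, rev == "1"))
    try:
        return MetabolicNetwork(edges)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_network(net: MetabolicNetwork, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# reaction_id\tsource\ttarget\treversible\n")
        for e in net.edges:
            fh.write(f"{e.reaction_id}\t{e.source}\t{e.target}\t{int(e.reversible)}\n")


class AbundanceMatrix:
    """Reaction × sample matrix of non-negative real counts."""

    def __init__(
        self,
        reaction_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts,
    ):
        self.reaction_ids = list(reaction_ids)
        self.sample_ids = list(sample_ids)
        self.counts = np.asarray(counts, dtype=float)
        if self.counts.shape != (len(self.reaction_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.reaction_ids)} reactions x {len(self.sample_ids)} samples"
            )
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            dup = _first_dup(self.reaction_ids)
            raise ValueError(f"duplicate reaction id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_dup(self.sample_ids)
            raise ValueError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("non-finite abundance value")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at reaction {self.reaction_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self._row_index = {r: i for i, r in enumerate(self.reaction_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row(self, reaction_id: str):
        return self.counts[self._row_index[reaction_id]]

    def row_indices(self, reaction_ids: Iterable[str]) -> list[int]:
        try:
            return [self._row_index[r] for r in reaction_ids]
        except KeyError as exc:
            raise KeyError(f"reaction {exc.args[0]!r} has no abundance row") from None

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self._row_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.reaction_ids, columns=self.sample_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return (
            self.reaction_ids == other.reaction_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"AbundanceMatrix({self.shape[0]} reactions x {self.shape[1]} samples)"


def _first_dup(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise AssertionError("no duplicate")


def read_abundance(path: str | os.PathLike) -> AbundanceMatrix:
    """Read a TSV abundance matrix (header = sample ids, col 1 = reaction ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(
                f"{path}: duplicate sample column {_first_dup(sample_ids)!r}"
            )
        reaction_ids = []
        rows = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(sample_ids) + 1} "
                    f"fields, got {len(parts)}"
                )
            reaction_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError:
                bad = next(x for x in parts[1:] if not _is_number(x))
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric cell {bad!r}"
                ) from None
    counts = np.asarray(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    try:
        return AbundanceMatrix(reaction_ids, sample_ids, counts)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_abundance(m: AbundanceMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\t" + "\t".join(m.sample_ids) + "\n")
        for rid, row in zip(m.reaction_ids, m.counts):
            fh.write(rid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


@dataclass(frozen=True)
class GroupDesign:
    """Two-group sample labelling (phenotype groups G1 and G2)."""

    assignment: Mapping[str, str]
    g1: str
    g2: str

    def __post_init__(self):
        labels = set(self.assignment.values())
        if self.g1 == self.g2:
            raise ValueError("group labels must be distinct")
        if labels != {self.g1, self.g2}:
            raise ValueError(
                f"assignment labels {sorted(labels)} do not match "
                f"({self.g1!r}, {self.g2!r})"
            )
        for g in (self.g1, self.g2):
            n = sum(1 for v in self.assignment.values() if v == g)
            if n < 2:
                raise ValueError(f"group {g!r} has {n} samples; need >= 2")

    @classmethod
    def from_table(cls, path: str | os.PathLike) -> "GroupDesign":
        """Read ``sample_id<TAB>group``; G1/G2 follow first appearance order."""
        assignment: dict[str, str] = {}
        order: list[str] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 2 fields, got {len(parts)}"
                    )
                sid, grp = parts
                if sid in assignment:
                    raise ValueError(f"{path}: line {lineno}: duplicate sample {sid!r}")
                assignment[sid] = grp
                if grp not in order:
                    order.append(grp)
        if len(order) != 2:
            raise ValueError(f"{path}: found {len(order)} group labels; need exactly 2")
        return cls(assignment, order[0], order[1])

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def indices(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of G1 and G2 samples within ``sample_ids``."""
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples not assigned to a group: {missing}")
        i1 = np.array(
            [i for i, s in enumerate(sample_ids) if self.assignment[s] == self.g1],
            dtype=int,
        )
        i2 = np.array(
            [i for i, s in enumerate(sample_ids) if self.assignment[s] == self.g2],
            dtype=int,
        )
        return i1, i2


def write_groups(d: GroupDesign, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid, grp in d.assignment.items():
            fh.write(f"{sid}\t{grp}\n")


def read_groups(path: str | os.PathLike) -> GroupDesign:
    return GroupDesign.from_table(path)


def counts_from_hits(
    hits: Mapping[str, str | os.PathLike] | str | os.PathLike,
    gene_to_reaction: str | os.PathLike,
    *,
    max_evalue: float = 1e-5,
    min_bitscore: float = 50.0,
    min_identity: float = 50.0,
    multimap: str = "full",
) -> tuple[AbundanceMatrix, dict]:
    """Build a reaction abundance matrix from BLAST tabular hits.

    ``hits`` is either a mapping ``sample_id -> path`` (one standard 12-column
    tabular file per sample) or a single path to a 13-column file whose first
    column is the sample id.  Each query contributes through its best hit only
    (highest bitscore; ties broken by lowest e-value, then first occurrence).
    Best hits failing the filters (e-value < ``max_evalue``, bitscore >
    ``min_bitscore``, %identity > ``min_identity``; strict comparisons) are
    dropped.  A gene mapping to m reactions adds 1 to each (``multimap="full"``)
    or 1/m to each (``multimap="fractional"``).

    Returns the matrix plus a summary dict (query totals and any best-hit
    genes absent from the mapping table — reported, never an error).
    """
    if multimap not in ("full", "fractional"):
        raise ValueError(f"multimap must be 'full' or 'fractional', got {multimap!r}")

    gene_map: dict[str, list[str]] = {}
    with open(gene_to_reaction) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            gene, reaction = line.split()[:2]
            gene_map.setdefault(gene, [])
            if reaction not in gene_map[gene]:
                gene_map[gene].append(reaction)

    # best hit per (sample, query): (bitscore desc, evalue asc, first occurrence)
    best: dict[tuple[str, str], tuple[float, float, int, str]] = {}
    n_rows = 0
    if isinstance(hits, (str, os.PathLike)):
        files = [(None, hits)]
    else:
        files = list(hits.items())
    sample_order: list[str] = []
    for sample, path in files:
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if sample is None:
                    sid, fields = parts[0], parts[1:]
                else:
                    sid, fields = sample, parts
                if len(fields) != 12:
                    raise ValueError(
                        f"{path}: expected 12 tabular hit fields, got {len(fields)}"
                    )
                if sid not in sample_order:
                    sample_order.append(sid)
                query, subject = fields[0], fields[1]
                identity = float(fields[2])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                n_rows += 1
                key = (sid, query)
                cand = (-bitscore, evalue, n_rows, subject, identity)
                if key not in best or cand < best[key]:
                    best[key] = cand

    reactions: set[str] = set()
    unmapped: set[str] = set()
    n_pass = 0
    contrib: dict[tuple[str, str], float] = {}
    for (sid, _query), (neg_bs, evalue, _ord, subject, identity) in best.items():
        bitscore = -neg_bs
        if not (evalue < max_evalue and bitscore > min_bitscore and identity > min_identity):
            continue
        n_pass += 1
        mapped = gene_map.get(subject)
        if not mapped:
            unmapped.add(subject)
            continue
        inc = 1.0 if multimap == "full" else 1.0 / len(mapped)
        for r in mapped:
            reactions.add(r)
            contrib[(sid, r)] = contrib.get((sid, r), 0.0) + inc

    reaction_ids = sorted(reactions)
    counts = np.zeros((len(reaction_ids), len(sample_order)))
    ridx = {r: i for i, r in enumerate(reaction_ids)}
    sidx = {s: j for j, s in enumerate(sample_order)}
    for (sid, r), v in contrib.items():
        counts[ridx[r], sidx[sid]] = v
    summary = {
        "queries_with_hits": len(best),
        "queries_passing_filter": n_pass,
        "unmapped_genes": sorted(unmapped),
    }
    return AbundanceMatrix(reaction_ids, sample_order, counts), summary


def reconcile(
    net: MetabolicNetwork, m: AbundanceMatrix
) -> AbundanceMatrix:
    """Align an abundance matrix with a network.

    Network edges with no abundance row receive an all-zero row (appended in
    lexicographic order), so they can never score positive; rows for reactions
    absent from the network are kept — they still get per-reaction statistics
    but are excluded from the search, which only walks network edges.
    """
    missing = sorted(set(net.edge_ids) - set(m.reaction_ids))
    if not missing:
        return m
    counts = np.vstack([m.counts, np.zeros((len(missing), len(m.sample_ids)))])
    return AbundanceMatrix(m.reaction_ids + missing, m.sample_ids, counts)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def subnetwork_dot(net: MetabolicNetwork, reaction_ids: Sequence[str]) -> str:
    """Graphviz DOT text for one subnetwork (edges labelled by reaction id)."""
    lines = ["digraph subnetwork {"]
    for rid in reaction_ids:
        e = net.edge(rid)
        attrs = f'label="{rid}"'
        if e.reversible:
            attrs += ", dir=both"
        lines.append(f'  "{e.source}" -> "{e.target}" [{attrs}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_report(
    results,
    stats,
    path: str | os.PathLike,
    *,
    network: MetabolicNetwork | None = None,
    dot: bool = False,
) -> None:
    """Write the discovery report under directory ``path``.

    Produces ``subnetworks.tsv`` (rank, p_abund, p_struct, k, score, enriched
    group, member reactions ranked by p_abund ascending), ``reactions.tsv``
    (per-reaction group means, p, Z, subnetwork membership) and, if ``dot`` is
    set, one DOT file per subnetwork for graph rendering.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in results:
        if math.isnan(r.p_abund) or math.isnan(r.p_struct):
            raise ValueError(
                f"NaN p-value for subnetwork {sorted(r.subnetwork.edges)}"
            )
    ordered = sorted(
        results, key=lambda r: (r.p_abund, r.p_struct, -abs(r.subnetwork.score))
    )

    member_of: dict[str, int] = {}
    with open(outdir / "subnetworks.tsv", "w") as fh:
        fh.write("rank\tp_abund\tp_struct\tk\tscore\tenriched_in\treactions\n")
        for rank, r in enumerate(ordered, start=1):
            for rid in r.subnetwork.edges:
                member_of.setdefault(rid, rank)
            fh.write(
                f"{rank}\t{_fmt(r.p_abund)}\t{_fmt(r.p_struct)}\t"
                f"{r.subnetwork.k}\t{_fmt(r.subnetwork.score)}\t"
                f"{r.enriched_in}\t{','.join(r.subnetwork.edges)}\n"
            )

    with open(outdir / "reactions.tsv", "w") as fh:
        fh.write("reaction_id\tmean_g1\tmean_g2\tp\tz\tsubnetwork\n")
        for s in stats:
            sub = member_of.get(s.reaction_id, "")
            fh.write(
                f"{s.reaction_id}\t{_fmt(s.mean_g1)}\t{_fmt(s.mean_g2)}\t"
                f"{_fmt(s.p)}\t{_fmt(s.z)}\t{sub}\n"
            )

    if dot:
        if network is None:
            raise ValueError("DOT output requires the network")
        for rank, r in enumerate(ordered, start=1):
            text = subnetwork_dot(network, r.subnetwork.edges)
            (outdir / f"subnetwork_{rank}.dot").write_text(text)
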
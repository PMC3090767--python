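import numpy as np
import pytest

from pathdiff.netio import MetabolicNetwork, ReactionEdge


@pytest.fixture
def path_network():
    """Compound path C0-C1-...-C5 with edges e1..e5 (all irreversible)."""
    return MetabolicNetwork(
        [ReactionEdge(f"e{i + 1}", f"C{i}", f"C{i + 1}") for i in range(5)]
    )


@pytest.fixture
def triangle_network():
    return MetabolicNetwork(
        [
            ReactionEdge("a", "X", "Y"),
            ReactionEdge("b", "Y", "Z"),
            ReactionEdge("c", "Z", "X"),
        ]
    )


def random_small_network(rng: np.random.Generator, max_edges: int = 12):
    """A small random network (possibly with reversible edges and cycles)."""
    n_c = int(rng.integers(4, 9))
    n_e = int(rng.integers(max(3, n_c - 1), max_edges + 1))
    comps = [f"C{i}" for i in range(n_c)]
    edges = []
    for i in range(n_e):
        if i < n_c - 1:
            u, v = comps[int(rng.integers(i + 1))], comps[i + 1]
        else:
            a, b = rng.choice(n_c, size=2, replace=False)
            u, v = comps[int(a)], comps[int(b)]
        if rng.random() < 0.5:
            u, v = v, u
        edges.append(ReactionEdge(f"R{i:02d}", u, v, bool(rng.random() < 0.5)))
    return MetabolicNetwork(edges)
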
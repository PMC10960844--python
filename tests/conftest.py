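import numpy as np
import pytest

from hypermi import Assignment, Hypergraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hypergraph():
    """Mixed-size simple hypergraph on 5 vertices."""
    return Hypergraph.from_edges([(0, 1), (0, 1, 2), (2, 3, 4), (3, 4)], n=5)


def random_hypergraph(rng, n, n_edges, sizes=(1, 2, 3), multisets=False):
    """Random (multi)hypergraph for randomized cross-checks."""
    edges = []
    for _ in range(n_edges):
        k = int(rng.choice(sizes))
        if multisets:
            e = tuple(sorted(rng.integers(0, n, size=k)))
        else:
            e = tuple(sorted(rng.choice(n, size=min(k, n), replace=False)))
        edges.append(e)
    return Hypergraph.from_edges(edges, n=n)


def random_assignment(rng, n, m):
    return Assignment(rng.integers(0, m, size=n), m)
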
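import numpy as np
import pytest

from memflow import DirectedGraph


@pytest.fixture
def triangle():
    """Unit-weight undirected triangle 1-2-3."""
    return DirectedGraph.from_edges([(1, 2), (2, 3), (3, 1)], undirected=True)


@pytest.fixture
def path3():
    """Unit-weight undirected path 1-2-3."""
    return DirectedGraph.from_edges([(1, 2), (2, 3)], undirected=True)


@pytest.fixture
def two_cliques():
    """Two 4-cliques joined by a single edge (0..3 and 4..7)."""
    edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
    edges += [(0, 4)]
    return DirectedGraph.from_edges(edges, undirected=True)


def random_connected_graph(rng: np.random.Generator, n: int = 8,
                           p: float = 0.4, weighted: bool = False):
    """Small connected undirected graph (ring + random chords)."""
    edges = [(i, (i + 1) % n) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if (i, j) not in ((0, n - 1),) and rng.random() < p:
                edges.append((i, j))
    if weighted:
        edges = [(i, j, float(rng.integers(1, 5))) for i, j in edges]
    return DirectedGraph.from_edges(edges, undirected=True)
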
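import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_weighted_edges_from([("A", "B", 0.3), ("B", "C", 0.3), ("A", "C", 0.3)])
    return g


@pytest.fixture
def two_triangles_bridge():
    """Two triangles joined by one near-zero-weight bridge."""
    g = nx.Graph()
    g.add_weighted_edges_from(
        [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0), (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0), (2, 3, 0.01)]
    )
    return g


@pytest.fixture
def two_k4():
    """Two disconnected 4-cliques with unit weights."""
    g = nx.Graph()
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(base + i, base + j, weight=1.0)
    return g


def random_weighted_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.05, 1.0))
    return g


@pytest.fixture
def rand_graph():
    return random_weighted_graph(30, 0.2, seed=7)
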
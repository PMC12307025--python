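import numpy as np
import pytest

from eegconn.omst import WeightedGraph


def random_connected_graph(rng: np.random.Generator, n: int,
                           density: float = 0.7) -> WeightedGraph:
    """Random connected weighted graph (retries until connected)."""
    from scipy.sparse.csgraph import connected_components
    while True:
        w = np.triu((rng.random((n, n)) < density) * rng.random((n, n)), 1)
        w = w + w.T
        if connected_components(w > 0, directed=False)[0] == 1:
            return WeightedGraph([f"n{i:02d}" for i in range(n)], w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return WeightedGraph(["A", "B", "C"], w)


@pytest.fixture
def two_cliques():
    """Two disconnected unit-weight 4-cliques on 8 nodes."""
    w = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return WeightedGraph([f"n{i}" for i in range(8)], w)
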
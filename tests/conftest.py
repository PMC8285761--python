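import numpy as np
import pytest

from graphmapper import AttributedGraph, fixtures


@pytest.fixture
def path3() -> AttributedGraph:
    return fixtures.standard_graphs("path", 3)


@pytest.fixture
def ring4() -> AttributedGraph:
    return fixtures.standard_graphs("ring", 4)


@pytest.fixture
def barbell33() -> AttributedGraph:
    return fixtures.standard_graphs("barbell", (3, 3))


@pytest.fixture
def triangle() -> AttributedGraph:
    return AttributedGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def spammer() -> AttributedGraph:
    return fixtures.spammer_graph(seed=0)


def random_graph(rng: np.random.Generator, n_max: int = 30, p: float = 0.3):
    """Small Erdos-Renyi helper shared by the oracle-based tests."""
    n = int(rng.integers(2, n_max + 1))
    edges = [
        (u, v)
        for u in range(n)
        for v in range(u + 1, n)
        if rng.random() < p
    ]
    return AttributedGraph.from_edges(n, edges)
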
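import numpy as np
import pytest

from costnet import BinaryGraph, WeightedNetwork, validate_weighted_network


@pytest.fixture
def triangle_net() -> WeightedNetwork:
    """3-node network with upper-triangle weights {0.9, 0.5, 0.1}."""
    w = np.array(
        [
            [0.0, 0.9, 0.5],
            [0.9, 0.0, 0.1],
            [0.5, 0.1, 0.0],
        ]
    )
    return validate_weighted_network(w)


@pytest.fixture
def path3() -> BinaryGraph:
    """Path graph 0-1-2."""
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
    return BinaryGraph(adjacency=a)


@pytest.fixture
def star4() -> BinaryGraph:
    """Star on 4 nodes: hub 0 connected to leaves 1..3."""
    a = np.zeros((4, 4), dtype=np.int8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return BinaryGraph(adjacency=a)


def complete_graph(n: int) -> BinaryGraph:
    a = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
    return BinaryGraph(adjacency=a)


def empty_graph(n: int) -> BinaryGraph:
    return BinaryGraph(adjacency=np.zeros((n, n), dtype=np.int8))


def transform_offdiag(net: WeightedNetwork, f) -> WeightedNetwork:
    """Apply an elementwise map to the off-diagonal weights only."""
    w = net.weights.copy()
    mask = ~np.eye(net.n_nodes, dtype=bool)
    w[mask] = f(w[mask])
    return validate_weighted_network(w)
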
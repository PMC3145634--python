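"""Efficiency metrics against hand enumeration and brute-force oracles."""

import itertools

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costnet import (
    BinaryGraph,
    NetworkError,
    global_efficiency,
    local_efficiency,
    make_cost_grid,
    random_weighted_network,
    shortest_path_matrix,
    threshold_profile,
    validate_weighted_network,
    weighted_cost,
    weighted_efficiency,
    weighted_shortest_path_matrix,
)
from conftest import complete_graph, empty_graph


def brute_force_hop_distances(adj: np.ndarray) -> np.ndarray:
    """Shortest hop counts by exhaustive enumeration of simple paths."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = range(n)
    for i, j in itertools.combinations(nodes, 2):
        best = np.inf
        others = [v for v in nodes if v not in (i, j)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (i, *mid, j)
                if all(adj[a, b] for a, b in zip(path, path[1:])):
                    best = min(best, len(path) - 1)
        d[i, j] = d[j, i] = best
    return d


def brute_force_weighted_distances(weights: np.ndarray) -> np.ndarray:
    """Weighted shortest paths (lengths 1/w) by exhaustive enumeration."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = range(n)
    for i, j in itertools.combinations(nodes, 2):
        best = np.inf
        others = [v for v in nodes if v not in (i, j)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (i, *mid, j)
                if all(weights[a, b] > 0 for a, b in zip(path, path[1:])):
                    length = sum(1.0 / weights[a, b] for a, b in zip(path, path[1:]))
                    best = min(best, length)
        d[i, j] = d[j, i] = best
    return d


def random_adjacency(n: int, p: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a = (rng.uniform(size=(n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


class TestShortestPaths:
    def test_two_hop_distance_on_path(self, path3):
        d = shortest_path_matrix(path3).lengths
        assert d[0, 2] == 2.0

    def test_empty_graph_all_unreachable(self):
        d = shortest_path_matrix(empty_graph(4)).lengths
        off = ~np.eye(4, dtype=bool)
        assert np.isinf(d[off]).all()
        assert (np.diagonal(d) == 0).all()

    def test_complete_graph_all_adjacent(self):
        d = shortest_path_matrix(complete_graph(5)).lengths
        off = ~np.eye(5, dtype=bool)
        assert (d[off] == 1.0).all()

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        a = random_adjacency(n, rng.uniform(0.1, 0.9), seed + 1000)
        d = shortest_path_matrix(BinaryGraph(adjacency=a)).lengths
        assert np.array_equal(d, brute_force_hop_distances(a))


class TestGlobalEfficiency:
    def test_complete_graph_is_maximally_efficient(self):
        for n in (3, 5, 8):
            assert global_efficiency(complete_graph(n)) == 1.0

    def test_empty_graph_has_zero_efficiency(self):
        assert global_efficiency(empty_graph(6)) == 0.0

    def test_path_graph_hand_enumeration(self, path3):
        # ordered-pair distances (1,1,1,1,2,2) -> mean reciprocal 5/6
        assert global_efficiency(path3) == pytest.approx(5 / 6, abs=1e-15)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_networkx(self, seed):
        a = random_adjacency(9, 0.4, seed)
        g = BinaryGraph(adjacency=a)
        assert global_efficiency(g) == pytest.approx(
            nx.global_efficiency(nx.from_numpy_array(a)), abs=1e-12
        )


class TestLocalEfficiency:
    def test_complete_graph(self):
        assert local_efficiency(complete_graph(4)) == 1.0

    def test_empty_graph_isolated_node_convention(self):
        assert local_efficiency(empty_graph(5)) == 0.0

    def test_star_graph_hub_and_leaves_score_zero(self, star4):
        # hub's neighbors are mutually unconnected; leaves have one neighbor
        assert local_efficiency(star4) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_networkx(self, seed):
        a = random_adjacency(9, 0.4, seed + 50)
        g = BinaryGraph(adjacency=a)
        assert local_efficiency(g) == pytest.approx(
            nx.local_efficiency(nx.from_numpy_array(a)), abs=1e-12
        )


def triangle_with_weak_edge():
    w = np.array([[0.0, 1.0, 0.4], [1.0, 0.0, 1.0], [0.4, 1.0, 0.0]])
    return validate_weighted_network(w)


class TestWeightedShortestPaths:
    def test_unit_weights_give_unit_lengths(self):
        w = np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        d = weighted_shortest_path_matrix(validate_weighted_network(w)).lengths
        off = ~np.eye(4, dtype=bool)
        assert (d[off] == 1.0).all()

    def test_detour_beats_weak_direct_edge(self):
        # direct length 1/0.4 = 2.5 vs two unit steps = 2
        d = weighted_shortest_path_matrix(triangle_with_weak_edge()).lengths
        assert d[0, 2] == pytest.approx(2.0, abs=1e-15)

    def test_strong_weights_make_direct_edges_geodesic(self):
        net = strong_random_net(seed=4)
        d = weighted_shortest_path_matrix(net).lengths
        off = ~np.eye(net.n_nodes, dtype=bool)
        assert d[off] == pytest.approx(1.0 / net.weights[off], abs=1e-15)

    def test_zero_weight_rejected_for_reciprocal_lengths(self):
        w = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.0]])
        with pytest.raises(NetworkError, match="fully weighted"):
            weighted_shortest_path_matrix(validate_weighted_network(w))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        net = random_weighted_network(n, seed=seed + 300)
        d = weighted_shortest_path_matrix(net).lengths
        assert d == pytest.approx(brute_force_weighted_distances(net.weights))


def strong_random_net(seed: int, n: int = 8):
    """Weights in [0.5, 1]: every direct edge is a weighted geodesic."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w[iu] = rng.uniform(0.5, 1.0, size=iu[0].shape[0])
    return validate_weighted_network(w + w.T)


class TestWeightedEfficiency:
    def test_saturated_unit_network(self):
        w = np.ones((5, 5))
        np.fill_diagonal(w, 0.0)
        assert weighted_efficiency(validate_weighted_network(w)) == 1.0

    def test_counterexample_differs_from_weighted_cost(self):
        net = triangle_with_weak_edge()
        assert weighted_efficiency(net) == pytest.approx(5 / 6, abs=1e-15)
        assert weighted_cost(net) == pytest.approx(0.8, abs=1e-15)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_equals_weighted_cost_when_direct_edges_dominate(self, seed):
        net = strong_random_net(seed)
        assert weighted_efficiency(net) == pytest.approx(
            weighted_cost(net), abs=1e-15
        )

    def test_bounded_in_unit_interval(self):
        for seed in range(5):
            net = random_weighted_network(7, seed=seed)
            assert 0.0 <= weighted_efficiency(net) <= 1.0


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_global_efficiency_is_monotone_along_the_grid(seed):
    net = random_weighted_network(10, seed=seed)
    grid = make_cost_grid(10)
    values = [
        global_efficiency(g) for g in threshold_profile(net, grid.levels)
    ]
    assert all(b >= a for a, b in zip(values, values[1:]))
    assert values[-1] == 1.0
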
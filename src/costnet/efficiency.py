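"""Shortest paths and efficiency metrics, unweighted and weighted.

Global efficiency is the average over ordered node pairs of the reciprocal
shortest-path length; disconnected pairs contribute zero, so the metric is
defined for any graph at any sparsity (unlike the characteristic path length,
which diverges on disconnected graphs).  Local efficiency averages, over
nodes, the global efficiency of each node's neighbor-induced subgraph, with
isolated and degree-one nodes contributing zero.

The weighted analogues replace hop counts by path lengths summed over
``phi(w)`` for a monotone decreasing map ``phi : (0, 1] -> [1, inf)``; the
reciprocal ``phi(w) = 1/w`` is the default.  With that choice every weighted
distance is at least 1, so weighted efficiency stays in [0, 1] — and whenever
every direct connection is itself a weighted shortest path (guaranteed when
``max(W) <= 2 * min(W)``) the weighted efficiency collapses to the weighted
cost exactly, which is why it is a poor stand-in for topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network import BinaryGraph, NetworkError, WeightedNetwork

__all__ = [
    "DistanceMatrix",
    "shortest_path_matrix",
    "global_efficiency",
    "local_efficiency",
    "weighted_shortest_path_matrix",
    "weighted_efficiency",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise shortest-path lengths; ``inf`` marks unreachable pairs."""

    lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]


def _bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances of a 0/1 adjacency matrix.

    Breadth-first search run simultaneously from all sources by iterated
    boolean matrix products: pairs first reachable at the k-th power of the
    adjacency matrix are at hop distance k.  Pairs never reached stay at inf.
    """
    n = adj.shape[0]
    a = adj.astype(bool)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    if not a.any():
        return d
    d[a] = 1.0
    reach = a | np.eye(n, dtype=bool)
    af = adj.astype(np.float64)
    hops = 1
    while hops < n:
        wider = (reach @ af) > 0
        new = wider & ~reach
        if not new.any():
            break
        hops += 1
        d[new] = hops
        reach |= new
    return d


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _global_efficiency_adj(adj: np.ndarray) -> float:
    return _efficiency_from_distances(_bfs_distances(adj))


def shortest_path_matrix(graph: BinaryGraph) -> DistanceMatrix:
    """Breadth-first hop distances; disconnected pairs are infinite."""
    return DistanceMatrix(lengths=_bfs_distances(graph.adjacency))


def global_efficiency(graph: BinaryGraph) -> float:
    """Mean reciprocal hop distance over ordered pairs, in [0, 1]."""
    return _global_efficiency_adj(graph.adjacency)


def _local_efficiency_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.shape[0] < 2:
            continue  # isolated and degree-1 nodes contribute 0
        sub = adj[np.ix_(nbrs, nbrs)]
        total += _global_efficiency_adj(sub)
    return total / n


def local_efficiency(graph: BinaryGraph) -> float:
    """Mean over nodes of the neighbor subgraph's global efficiency.

    The neighbor subgraph of node i is the subgraph induced by the nodes
    adjacent to i (excluding i itself), normalized by its own ordered-pair
    count; subgraphs with fewer than two nodes score zero.
    """
    return _local_efficiency_adj(graph.adjacency)


PhiMap = Callable[[np.ndarray], np.ndarray]


def _reciprocal(w: np.ndarray) -> np.ndarray:
    return 1.0 / w


def _weighted_lengths(net: WeightedNetwork, phi: PhiMap | None) -> np.ndarray:
    if not net.standardized:
        raise NetworkError("weighted shortest paths require standardized weights")
    w = net.weights
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    if (w[off] <= 0.0).any():
        raise NetworkError(
            "weighted shortest paths require a fully weighted network "
            "(strictly positive off-diagonal weights)"
        )
    lengths = np.zeros_like(w)
    lengths[off] = (_reciprocal if phi is None else phi)(w[off])
    if (lengths[off] <= 0.0).any():
        raise NetworkError("phi must map weights to positive edge lengths")
    return lengths


def weighted_shortest_path_matrix(
    net: WeightedNetwork, phi: PhiMap | None = None
) -> DistanceMatrix:
    """Dijkstra distances on edge lengths ``phi(w)`` (default ``1/w``).

    Any decreasing ``phi`` into the positive reals is accepted, but only maps
    into ``[1, inf)`` (such as the default) keep the weighted efficiency in
    [0, 1] and support the weighted-cost equivalence result.
    """
    lengths = _weighted_lengths(net, phi)
    d = dijkstra(csr_matrix(lengths), directed=False)
    return DistanceMatrix(lengths=d)


def weighted_efficiency(net: WeightedNetwork, phi: PhiMap | None = None) -> float:
    """Mean reciprocal weighted shortest-path length over ordered pairs."""
    d = weighted_shortest_path_matrix(net, phi=phi)
    return _efficiency_from_distances(d.lengths)
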
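"""Synthetic fixtures: random networks, proportional pairs, layered matrices.

These generators reproduce, at configurable size, the worked constructions
that motivate cost-integration:

* proportional pairs — two association matrices differing only by a scalar
  factor: their weighted costs differ by exactly that factor while every
  thresholded graph, and hence every cost-integrated metric, coincides;
* two-node pairs — the smallest cost grid (a single level), on which every
  network attains uniformly cost-integrated global efficiency 1;
* layered matrices — weights assigned in strictly decreasing rank order so
  that the thresholded graph grows through prescribed topological bands
  (ring-lattice "regular" or seeded uniform "random"), emulating a
  small-world-derived matrix whose topology varies with wiring cost.  Two
  layer specifications sharing a band produce identical thresholded graphs
  at every cost inside that band.

Because cost-integration depends on the weights only through their ranks,
any strictly decreasing weight sequence consistent with the target rank
order yields the same integrated topology; the generators use the sequence
``(M - k + 1) / (M + 1)``, which keeps all weights inside (0, 1) and tie-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import NetworkError, WeightedNetwork, make_cost_grid

__all__ = [
    "LayerSpec",
    "random_weighted_network",
    "proportional_pair",
    "two_node_pair",
    "lattice_band_edges",
    "layered_association_matrix",
    "thirds_spec",
]


def random_weighted_network(n_nodes: int, seed: int) -> WeightedNetwork:
    """Symmetric matrix with i.i.d. uniform (0, 1) off-diagonal weights."""
    if n_nodes < 2:
        raise NetworkError("a network needs at least 2 nodes")
    rng = np.random.default_rng(seed)
    m = n_nodes * (n_nodes - 1) // 2
    flat = rng.uniform(0.0, 1.0, size=m)
    w = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    w[iu] = flat
    w = w + w.T
    w.flags.writeable = False
    return WeightedNetwork(weights=w, standardized=True)


def proportional_pair(
    base: WeightedNetwork, factor: float
) -> tuple[WeightedNetwork, WeightedNetwork]:
    """A network and its scalar multiple ``factor * W`` (factor in (0, 1)).

    The pair has weighted costs in exact ratio ``factor`` but identical
    threshold profiles: scaling is a strictly increasing transform, so the
    same edge sets are selected at every cost.
    """
    if not base.standardized:
        raise NetworkError("proportional pairs require a standardized base")
    if not 0.0 < factor < 1.0:
        raise NetworkError("factor must lie strictly inside (0, 1)")
    scaled = base.weights * factor
    scaled.flags.writeable = False
    return base, WeightedNetwork(weights=scaled, standardized=True)


def two_node_pair(
    w1: float, w2: float
) -> tuple[WeightedNetwork, WeightedNetwork]:
    """Two 2-node networks with single off-diagonal weights w1, w2 in (0, 1)."""
    nets = []
    for w in (w1, w2):
        if not 0.0 < w < 1.0:
            raise NetworkError("two-node weights must lie strictly inside (0, 1)")
        mat = np.array([[0.0, w], [w, 0.0]])
        mat.flags.writeable = False
        nets.append(WeightedNetwork(weights=mat, standardized=True))
    return nets[0], nets[1]


def _lattice_order(n_nodes: int) -> list[tuple[int, int]]:
    """All pairs ordered by ring distance, then lexicographic index."""
    pairs: list[tuple[int, int]] = []
    for d in range(1, n_nodes // 2 + 1):
        band = set()
        for i in range(n_nodes):
            j = (i + d) % n_nodes
            band.add((min(i, j), max(i, j)))
        pairs.extend(sorted(band))
    return pairs


def lattice_band_edges(
    n_nodes: int, k_start: int, k_end: int
) -> list[tuple[int, int]]:
    """Ring-lattice edges with ranks ``k_start..k_end`` (1-based, inclusive).

    Edges are ordered by increasing ring distance, nearest neighbors first,
    with lexicographic index order inside each distance class; the first N
    edges form the ring itself and the full range saturates the graph.
    """
    m = n_nodes * (n_nodes - 1) // 2
    if not 1 <= k_start <= k_end <= m:
        raise NetworkError(f"rank band must satisfy 1 <= start <= end <= {m}")
    return _lattice_order(n_nodes)[k_start - 1 : k_end]


@dataclass(frozen=True)
class LayerSpec:
    """Partition of the cost range (0, 1] into topological bands.

    ``boundaries`` are ascending grid costs ending at 1; band b spans the
    grid levels in ``(boundaries[b-1], boundaries[b]]`` (with an implicit 0
    on the left).  ``topologies`` tags each band ``regular`` or ``random``.
    """

    boundaries: tuple[float, ...]
    topologies: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundaries", tuple(float(b) for b in self.boundaries))
        object.__setattr__(self, "topologies", tuple(self.topologies))
        if len(self.boundaries) != len(self.topologies):
            raise NetworkError("need one topology tag per band")
        if not self.boundaries or abs(self.boundaries[-1] - 1.0) > 1e-12:
            raise NetworkError("band boundaries must end at 1")
        if any(b <= a for a, b in zip(self.boundaries, self.boundaries[1:])):
            raise NetworkError("band boundaries must be strictly increasing")
        bad = set(self.topologies) - {"regular", "random"}
        if bad:
            raise NetworkError(f"unknown band topologies: {sorted(bad)}")


def thirds_spec(topologies: Sequence[str], seed: int = 0) -> LayerSpec:
    """Convenience three-band spec with boundaries at thirds of the grid."""
    if len(topologies) != 3:
        raise NetworkError("thirds_spec takes exactly three band tags")
    return LayerSpec(boundaries=(1 / 3, 2 / 3, 1.0), topologies=tuple(topologies), seed=seed)


def layered_association_matrix(n_nodes: int, spec: LayerSpec) -> WeightedNetwork:
    """Association matrix realizing a banded topological construction.

    Weights decrease strictly with rank, so thresholding at any grid cost c
    inside band b yields exactly the band pattern's first ``c * M`` edges:
    regular bands consume ring-lattice edges in lattice order (skipping pairs
    already used), random bands draw uniformly without replacement from the
    unused pairs.  Specs sharing a leading band therefore produce identical
    thresholded graphs throughout that band.
    """
    grid = make_cost_grid(n_nodes)
    m = grid.m
    ks = [grid.index_of(b) for b in spec.boundaries]
    if ks[-1] != m:
        raise NetworkError("final band must end at cost 1")
    rng = np.random.default_rng(spec.seed)
    pair_index = {}
    iu, ju = np.triu_indices(n_nodes, k=1)
    for idx, (i, j) in enumerate(zip(iu, ju)):
        pair_index[(int(i), int(j))] = idx
    used = np.zeros(m, dtype=bool)
    order = np.empty(m, dtype=int)  # order[rank-1] = pair index
    lattice = [pair_index[p] for p in _lattice_order(n_nodes)]
    lattice_pos = 0
    filled = 0
    for band, k_end in zip(spec.topologies, ks):
        need = k_end - filled
        if band == "regular":
            taken = 0
            while taken < need:
                if lattice_pos >= m:
                    raise NetworkError("regular band exhausted the lattice ordering")
                e = lattice[lattice_pos]
                lattice_pos += 1
                if used[e]:
                    continue
                order[filled + taken] = e
                used[e] = True
                taken += 1
        else:
            free = np.flatnonzero(~used)
            if free.shape[0] < need:
                raise NetworkError("random band cannot be filled: pairs exhausted")
            chosen = rng.choice(free, size=need, replace=False)
            order[filled : filled + need] = chosen
            used[chosen] = True
        filled = k_end
    # strictly decreasing tie-free weights in (0, 1) by rank
    weights_flat = np.empty(m)
    weights_flat[order] = (m - np.arange(m)) / (m + 1)
    w = np.zeros((n_nodes, n_nodes))
    w[iu, ju] = weights_flat
    w = w + w.T
    w.flags.writeable = False
    return WeightedNetwork(weights=w, standardized=True)
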
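"""Graph containers, weight standardization, and cost measures.

A weighted undirected network is held as a symmetric ``N x N`` association
matrix with a zero diagonal.  Weights standardized to the unit interval are
interpreted as association strength, with larger values meaning stronger
association.  The *weighted cost* (connectivity strength) of such a network is
the mean of its off-diagonal entries; the *cost* (density) of an unweighted
graph is its edge count relative to the saturated count ``M = N(N-1)/2``.

The achievable costs of a thresholded graph form the discrete grid
``{k/M : k = 1..M}``.  The null cost is excluded: an edgeless graph carries no
topology, and keeping it would deflate cost-integrated metrics of every
network by the same uninformative atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkError",
    "WeightedNetwork",
    "BinaryGraph",
    "CostGrid",
    "validate_weighted_network",
    "standardize_correlations",
    "weighted_cost",
    "binary_cost",
    "make_cost_grid",
]


class NetworkError(ValueError):
    """Raised when an input violates a network contract."""


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric association matrix with zero diagonal.

    Parameters
    ----------
    weights
        ``N x N`` real matrix, symmetric, zero diagonal.
    standardized
        True iff every off-diagonal weight lies in ``[0, 1]``.  Rank-based
        operations (thresholding, cost-integration) accept unstandardized
        networks; weighted cost and weighted efficiency do not.
    """

    weights: np.ndarray
    standardized: bool = field(default=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkError("weights must be a square matrix")
        if w.shape[0] < 2:
            raise NetworkError("a network needs at least 2 nodes")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pairs(self) -> int:
        """Saturated edge count M = N(N-1)/2."""
        n = self.n_nodes
        return n * (n - 1) // 2

    def upper_triangle(self) -> np.ndarray:
        """The M weights above the diagonal, in row-major (i, j) order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]


@dataclass(frozen=True)
class BinaryGraph:
    """Unweighted undirected graph as a 0/1 adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkError("adjacency must be a square matrix")
        if a.shape[0] < 2:
            raise NetworkError("a graph needs at least 2 nodes")
        if not np.isin(a, (0, 1)).all():
            raise NetworkError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8, copy=False)
        if (np.diagonal(a) != 0).any():
            raise NetworkError("adjacency diagonal must be zero")
        if (a != a.T).any():
            raise NetworkError("adjacency must be symmetric")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def n_pairs(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def edge_list(self) -> np.ndarray:
        """Edges as an (n_edges, 2) array of 0-based (i, j) pairs, i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j])


@dataclass(frozen=True)
class CostGrid:
    """Ordered support {k/M : k = 1..M} of achievable non-null costs."""

    n_nodes: int
    levels: np.ndarray

    @property
    def m(self) -> int:
        """Number of grid levels (= saturated edge count)."""
        return self.levels.shape[0]

    def index_of(self, cost: float) -> int:
        """Edge count k for a grid level ``cost = k/M``.

        Off-grid values are rejected, not rounded: exactness of the
        thresholded cost is part of the contract.
        """
        m = self.m
        k = int(round(float(cost) * m))
        if not 1 <= k <= m or abs(cost * m - k) > 1e-6:
            raise NetworkError(
                f"cost {cost!r} is not on the {m}-level grid for "
                f"{self.n_nodes} nodes"
            )
        return k

    def __contains__(self, cost: float) -> bool:
        try:
            self.index_of(cost)
        except NetworkError:
            return False
        return True


def make_cost_grid(n_nodes: int) -> CostGrid:
    """Build the cost grid {k/M} for a network of ``n_nodes`` vertices."""
    if n_nodes < 2:
        raise NetworkError("a network needs at least 2 nodes")
    m = n_nodes * (n_nodes - 1) // 2
    levels = np.arange(1, m + 1, dtype=float) / m
    levels.flags.writeable = False
    return CostGrid(n_nodes=n_nodes, levels=levels)


def _is_standardized(weights: np.ndarray) -> bool:
    n = weights.shape[0]
    off = weights[~np.eye(n, dtype=bool)]
    return bool((off >= 0.0).all() and (off <= 1.0).all())


def validate_weighted_network(
    matrix: np.ndarray, tolerance: float = 1e-8
) -> WeightedNetwork:
    """Validate a raw association matrix into a :class:`WeightedNetwork`.

    Symmetry is enforced by averaging with the transpose when the asymmetry
    is within ``tolerance`` (relative to the largest magnitude entry); the
    diagonal is always zeroed, since topology and cost depend only on the
    off-diagonal elements.
    """
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise NetworkError("association matrix must be square")
    if w.shape[0] < 2:
        raise NetworkError("a network needs at least 2 nodes")
    if not np.isfinite(w).all():
        raise NetworkError("association matrix contains non-finite entries")
    scale = max(1.0, float(np.abs(w).max()))
    asym = float(np.abs(w - w.T).max())
    if asym > tolerance * scale:
        raise NetworkError(
            f"matrix asymmetry {asym:.3g} exceeds tolerance {tolerance:.3g}"
        )
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    w.flags.writeable = False
    return WeightedNetwork(weights=w, standardized=_is_standardized(w))


def standardize_correlations(
    matrix: np.ndarray, method: str = "absolute"
) -> WeightedNetwork:
    """Map a correlation matrix into standardized weights in [0, 1].

    ``absolute`` uses ``w = |r|``; ``affine`` uses ``w = (r + 1) / 2``.  Both
    turn negative correlations into positive association strengths, but they
    order mixed-sign entries differently, so the choice can change edge ranks;
    it is therefore an explicit argument and is echoed in all CLI reports.
    """
    r = np.asarray(matrix, dtype=float)
    net = validate_weighted_network(r)
    r = net.weights
    if (np.abs(r) > 1.0 + 1e-12).any():
        raise NetworkError("correlation entries must lie in [-1, 1]")
    if method == "absolute":
        w = np.abs(r)
    elif method == "affine":
        w = (r + 1.0) / 2.0
    else:
        raise NetworkError(f"unknown standardization method {method!r}")
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    w.flags.writeable = False
    return WeightedNetwork(weights=w, standardized=True)


def weighted_cost(net: WeightedNetwork) -> float:
    """Mean of the off-diagonal weights (connectivity strength).

    Equals the mean of the M upper-triangle weights by symmetry.  Requires a
    standardized network so that the value is comparable across analyses.
    """
    if not net.standardized:
        raise NetworkError("weighted cost requires standardized weights in [0, 1]")
    return float(net.upper_triangle().mean())


def binary_cost(graph: BinaryGraph) -> float:
    """Edge count relative to the saturated count: N_E / M."""
    return graph.n_edges / graph.n_pairs
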
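"""File I/O: dense association matrices and weighted edge lists.

Dense matrices are headerless delimited text (comma or tab/whitespace,
sniffed on read), N rows by N columns, written at full double precision so
write-then-read round-trips exactly.  Edge lists carry three columns
(node_i, node_j, weight) with 0-based indices and each undirected pair
listed once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .network import NetworkError, WeightedNetwork, validate_weighted_network

__all__ = [
    "read_dense_matrix",
    "write_dense_matrix",
    "read_edge_list",
    "write_edge_list",
    "load_network",
]


def read_dense_matrix(path: str | Path) -> np.ndarray:
    """Read a headerless N x N delimited matrix (comma or whitespace)."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise NetworkError(f"{path}: expected a square matrix, got {mat.shape}")
    return mat


def write_dense_matrix(
    path: str | Path, matrix: np.ndarray, delimiter: str = ","
) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.17g", delimiter=delimiter)


def read_edge_list(path: str | Path, n_nodes: int | None = None) -> np.ndarray:
    """Read a (node_i, node_j, weight) edge list into a dense matrix.

    Node indices are 0-based; each undirected pair appears once.  ``n_nodes``
    defaults to one more than the largest index seen.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    raw = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if raw.shape[1] != 3:
        raise NetworkError(f"{path}: edge lists need exactly 3 columns")
    i = raw[:, 0].astype(int)
    j = raw[:, 1].astype(int)
    if n_nodes is None:
        n_nodes = int(max(i.max(), j.max())) + 1
    if (i < 0).any() or (j < 0).any() or (i >= n_nodes).any() or (j >= n_nodes).any():
        raise NetworkError(f"{path}: node indices out of range for {n_nodes} nodes")
    if (i == j).any():
        raise NetworkError(f"{path}: self-loops are not allowed")
    w = np.zeros((n_nodes, n_nodes))
    seen = set()
    for a, b, x in zip(i, j, raw[:, 2]):
        key = (min(a, b), max(a, b))
        if key in seen:
            raise NetworkError(f"{path}: pair {key} listed more than once")
        seen.add(key)
        w[a, b] = x
        w[b, a] = x
    return w


def write_edge_list(path: str | Path, net: WeightedNetwork, delimiter: str = "\t") -> None:
    """Write the upper-triangle pairs as (i, j, weight) rows."""
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    with Path(path).open("w") as fh:
        for a, b in zip(iu, ju):
            fh.write(
                f"{a}{delimiter}{b}{delimiter}{net.weights[a, b]:.17g}\n"
            )


def load_network(
    path: str | Path,
    fmt: str = "auto",
    n_nodes: int | None = None,
    tolerance: float = 1e-8,
) -> WeightedNetwork:
    """Load a network from a dense matrix or edge-list file.

    ``fmt='auto'`` treats 3-column files as edge lists and anything else as a
    dense matrix.
    """
    path = Path(path)
    if fmt == "auto":
        with path.open() as fh:
            first = fh.readline()
        cols = len(first.replace(",", " ").split())
        if cols != 3:
            fmt = "dense"
        else:
            # 3 columns is ambiguous: a symmetric zero-diagonal 3x3 block is
            # a dense matrix, anything else is an edge list
            delimiter = "," if "," in first else None
            raw = np.loadtxt(path, delimiter=delimiter, ndmin=2)
            square = (
                raw.shape == (3, 3)
                and np.allclose(raw, raw.T)
                and np.allclose(np.diagonal(raw), 0.0)
            )
            fmt = "dense" if square else "edgelist"
    if fmt == "dense":
        mat = read_dense_matrix(path)
    elif fmt == "edgelist":
        mat = read_edge_list(path, n_nodes=n_nodes)
    else:
        raise NetworkError(f"unknown format {fmt!r}")
    return validate_weighted_network(mat, tolerance=tolerance)
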
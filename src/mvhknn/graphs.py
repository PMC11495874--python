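"""Similarity views, mutual-KNN adjacency, and normalized graph Laplacians.

For each test sample and class the solver builds a small graph over the K
nearest same-class training points. An edge (f, g) exists only when f and
g are *mutual* K-nearest neighbours; its weight is one of three pairwise
similarities (an RBF kernel, cosine similarity, or the Pearson
correlation), giving one graph "view" per similarity. Each view is turned
into a symmetric normalized Laplacian whose quadratic form penalizes
reconstruction weights that differ across similar neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConfigurationError,
    ContractViolationError,
    DegenerateInputError,
)

__all__ = [
    "VIEW_NAMES",
    "SimilarityView",
    "AdjacencyMatrix",
    "NormalizedLaplacian",
    "similarity",
    "mutual_knn_adjacency",
    "normalized_laplacian",
    "build_view_laplacians",
]

VIEW_NAMES = ("rbf", "cosine", "pearson")


@dataclass(frozen=True)
class SimilarityView:
    """One similarity measure.

    ``gamma`` is the RBF width; ``None`` means the scale-free default
    ``1/d`` resolved against the vectors at evaluation time. It is ignored
    by the cosine and Pearson views.
    """

    name: str
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.name not in VIEW_NAMES:
            raise ConfigurationError(
                f"unknown similarity view {self.name!r}; expected one of {VIEW_NAMES}"
            )
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigurationError("rbf gamma must be > 0")


@dataclass
class AdjacencyMatrix:
    """Mutual-KNN similarity weights over K neighbour nodes."""

    weights: np.ndarray          # (K, K), symmetric, >= 0, zero diagonal
    node_indices: np.ndarray     # training-set indices of the K nodes

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_indices = np.asarray(self.node_indices, dtype=int)


@dataclass
class NormalizedLaplacian:
    matrix: np.ndarray  # (K, K) symmetric PSD, eigenvalues in [0, 2]
    view_name: str


def similarity(x_i: np.ndarray, x_j: np.ndarray, view: SimilarityView) -> float:
    """Pairwise similarity of two feature vectors under one view.

    rbf: exp(-gamma * ||x_i - x_j||^2), in (0, 1].
    cosine: x_i.x_j / (||x_i|| ||x_j||), in [-1, 1].
    pearson: correlation of the two vectors over their d coordinates,
    in [-1, 1]; needs d >= 2 and non-constant vectors.
    """
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.shape != x_j.shape:
        raise ContractViolationError(
            f"vectors differ in dimension: {x_i.shape} vs {x_j.shape}"
        )
    d = x_i.size
    if d < 1:
        raise ContractViolationError("empty vectors")

    if view.name == "rbf":
        g = view.gamma if view.gamma is not None else 1.0 / d
        diff = x_i - x_j
        return float(np.exp(-g * float(diff @ diff)))

    if view.name == "cosine":
        ni = float(np.linalg.norm(x_i))
        nj = float(np.linalg.norm(x_j))
        if ni == 0.0 or nj == 0.0:
            raise DegenerateInputError("cosine similarity undefined for a zero vector")
        return float(x_i @ x_j / (ni * nj))

    # pearson
    if d < 2:
        raise DegenerateInputError("pearson correlation needs dimension >= 2")
    ci = x_i - x_i.mean()
    cj = x_j - x_j.mean()
    ni = float(np.linalg.norm(ci))
    nj = float(np.linalg.norm(cj))
    if ni == 0.0 or nj == 0.0:
        raise DegenerateInputError("pearson correlation undefined for a constant vector")
    return float(ci @ cj / (ni * nj))


def _knn_lists(points: np.ndarray, pool: np.ndarray, pool_positions: np.ndarray,
               k: int) -> list[set]:
    """Euclidean k-nearest lists (as position sets within *pool*) for each
    row of *points*, excluding each point's own pool position; ties broken
    by lower pool position."""
    m = pool.shape[0]
    k_eff = min(k, m - 1)
    lists: list[set] = []
    for row, self_pos in zip(points, pool_positions):
        dist = np.linalg.norm(pool - row[None, :], axis=1)
        dist[self_pos] = np.inf
        order = np.argsort(dist, kind="stable")
        lists.append(set(order[:k_eff].tolist()))
    return lists


def mutual_knn_adjacency(
    neighborhood,
    class_pool: np.ndarray,
    view: SimilarityView,
    K: int,
    mutual_scope: str = "class",
) -> AdjacencyMatrix:
    """Similarity weights among K neighbours, masked by KNN mutuality.

    Entry (f, g) is ``similarity(f, g)`` (negative values clamped to 0)
    when node f appears in node g's K-nearest list *and* vice versa;
    otherwise 0. With ``mutual_scope="class"`` (default) each node's
    K-nearest list is computed over the whole class training subset
    ``class_pool``; ``"neighborhood"`` restricts the lists to the K
    neighbourhood nodes themselves. The diagonal is always 0.
    """
    if mutual_scope not in ("class", "neighborhood"):
        raise ConfigurationError(f"unknown mutual_scope {mutual_scope!r}")
    class_pool = np.asarray(class_pool, dtype=float)
    if K > class_pool.shape[0]:
        raise ConfigurationError(
            f"K={K} exceeds the class pool size {class_pool.shape[0]}"
        )
    V = np.asarray(neighborhood.V, dtype=float)  # (d, K)
    nodes = V.T                                  # (K, d)
    k_nodes = nodes.shape[0]

    if mutual_scope == "class":
        pool = class_pool
        pool_positions = np.asarray(neighborhood.class_positions, dtype=int)
    else:
        pool = nodes
        pool_positions = np.arange(k_nodes)

    lists = _knn_lists(nodes, pool, pool_positions, K)

    W = np.zeros((k_nodes, k_nodes))
    for f in range(k_nodes):
        for g in range(f + 1, k_nodes):
            pf, pg = pool_positions[f], pool_positions[g]
            if pg in lists[f] and pf in lists[g]:
                s = similarity(nodes[f], nodes[g], view)
                W[f, g] = W[g, f] = max(s, 0.0)  # Laplacian needs weights >= 0
    return AdjacencyMatrix(weights=W, node_indices=np.asarray(neighborhood.indices))


def normalized_laplacian(W, view_name: str = "") -> NormalizedLaplacian:
    """Symmetric normalized Laplacian of a weighted graph.

    With degrees ``D_ii = sum_j W_ij``:
    ``L_ii = 1`` where ``D_ii != 0`` (else 0), and
    ``L_ij = -W_ij / sqrt(D_ii D_jj)`` where i and j are adjacent.
    Isolated nodes contribute zero rows, so the spectrum stays in [0, 2].
    """
    if isinstance(W, AdjacencyMatrix):
        if not view_name:
            view_name = ""
        W = W.weights
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ContractViolationError("adjacency must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ContractViolationError("adjacency must be symmetric")
    if np.any(W < 0):
        raise ContractViolationError("adjacency weights must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ContractViolationError("adjacency diagonal must be zero")

    deg = W.sum(axis=1)
    k = W.shape[0]
    L = np.zeros((k, k))
    nz = deg > 0
    L[np.diag_indices(k)] = nz.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sqrt = np.where(nz, 1.0 / np.sqrt(np.where(nz, deg, 1.0)), 0.0)
    off = -W * np.outer(inv_sqrt, inv_sqrt)
    off[np.diag_indices(k)] = 0.0
    L += off
    L = 0.5 * (L + L.T)  # kill rounding asymmetry
    return NormalizedLaplacian(matrix=L, view_name=view_name)


def build_view_laplacians(
    neighborhood,
    class_pool: np.ndarray,
    views: list[SimilarityView],
    K: int,
    mutual_scope: str = "class",
) -> list[NormalizedLaplacian]:
    """One normalized Laplacian per similarity view over the same K nodes.

    Each view's adjacency uses that view's own similarity for its weights.
    """
    laps = []
    for v in views:
        A = mutual_knn_adjacency(neighborhood, class_pool, v, K, mutual_scope)
        laps.append(normalized_laplacian(A.weights, view_name=v.name))
    return laps
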
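r"""Local-hyperplane nearest-neighbour classification (HKNN) and plain KNN.

HKNN classifies a query x by, for each class c, collecting the K
Euclidean-nearest training points of that class, spanning the local
hyperplane ``{ V_c alpha : alpha in R^K }`` with their feature vectors as
columns of ``V_c``, and scoring

    S_c(x) = lambda_r ||alpha||^2 + ||x - V_c alpha||^2

at the minimizing alpha. The query is assigned to the class whose local
hyperplane is closest. ``lambda_r = 0`` gives the plain normal-equation
solve; a positive ridge stabilizes rank-deficient neighbourhoods.

These two classifiers are the bottom rungs of the ablation ladder; the
robust solver in :mod:`mvhknn.solver` replaces the squared reconstruction
error with the KRP loss and adds a fused-graph penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import FeatureDataset
from .exceptions import ConfigurationError, SingularSystemWarning

__all__ = [
    "ClassNeighborhood",
    "find_neighborhood",
    "hknn_solve",
    "hknn_score",
    "hknn_classify",
    "knn_classify",
]

@dataclass
class ClassNeighborhood:
    """K nearest same-class training points of one query.

    ``V`` stores the neighbours as columns (shape ``(d, K)``);
    ``indices`` are their positions in the full training set,
    ``class_positions`` their positions within the class-c subset, and
    ``distances`` the corresponding Euclidean distances in ascending order.
    """

    class_label: int
    V: np.ndarray
    indices: np.ndarray
    class_positions: np.ndarray
    distances: np.ndarray

    @property
    def K(self) -> int:
        return self.V.shape[1]


def find_neighborhood(x: np.ndarray, data: FeatureDataset, c: int,
                      K: int) -> ClassNeighborhood:
    """K Euclidean-nearest class-c training points of x.

    Distance ties are broken by the lower training index (stable sort).
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    idx = data.class_indices(c)
    if idx.size < K:
        raise ConfigurationError(
            f"class {int(c)} has {idx.size} training samples but K={K}"
        )
    sub = data.X[idx]
    dist = np.linalg.norm(sub - x[None, :], axis=1)
    order = np.argsort(dist, kind="stable")[:K]
    return ClassNeighborhood(
        class_label=int(c),
        V=sub[order].T.copy(),
        indices=idx[order],
        class_positions=order,
        distances=dist[order],
    )


def hknn_solve(x: np.ndarray, nb: ClassNeighborhood,
               lambda_r: float = 0.0) -> np.ndarray:
    """Reconstruction weights minimizing the (ridge) hyperplane distance.

    Solves ``(lambda_r I + V^T V) alpha = V^T x``. At ``lambda_r = 0`` a
    singular Gram matrix triggers a least-norm fallback and a
    :class:`SingularSystemWarning`.
    """
    if lambda_r < 0:
        raise ConfigurationError("lambda_r must be >= 0")
    x = np.asarray(x, dtype=float).ravel()
    V = nb.V
    G = V.T @ V + lambda_r * np.eye(nb.K)
    b = V.T @ x
    if lambda_r == 0.0 and np.linalg.matrix_rank(V) < nb.K:
        warnings.warn(
            "singular hyperplane system at lambda_r=0; returning the "
            "least-norm solution",
            SingularSystemWarning,
        )
        return np.linalg.lstsq(V, x, rcond=None)[0]
    return np.linalg.solve(G, b)


def hknn_score(x: np.ndarray, nb: ClassNeighborhood, alpha: np.ndarray,
               lambda_r: float = 0.0) -> float:
    """``lambda_r ||alpha||^2 + ||x - V alpha||^2`` (squared hyperplane
    proximity)."""
    x = np.asarray(x, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    r = x - nb.V @ alpha
    return float(lambda_r * (alpha @ alpha) + r @ r)


def hknn_classify(x: np.ndarray, data: FeatureDataset, K: int,
                  lambda_r: float = 0.0):
    """Label of the nearest local hyperplane, plus all class scores.

    Returns ``(label, scores)`` with ``scores`` ordered by ascending class
    label; score ties resolve to the lowest label.
    """
    classes = data.classes
    if classes.size == 0:
        raise ConfigurationError("no labelled training samples")
    scores = np.empty(classes.size)
    for i, c in enumerate(classes):
        nb = find_neighborhood(x, data, int(c), K)
        alpha = hknn_solve(x, nb, lambda_r)
        scores[i] = hknn_score(x, nb, alpha, lambda_r)
    return int(classes[int(np.argmin(scores))]), scores


def knn_classify(x: np.ndarray, data: FeatureDataset, K: int) -> int:
    """Majority label among the K Euclidean-nearest training points.

    Vote ties resolve to the lowest class index; neighbour-distance ties
    to the lower training index.
    """
    if data.n == 0:
        raise ConfigurationError("empty training set")
    if K > data.n:
        raise ConfigurationError(f"K={K} exceeds the training size {data.n}")
    x = np.asarray(x, dtype=float).ravel()
    dist = np.linalg.norm(data.X - x[None, :], axis=1)
    order = np.argsort(dist, kind="stable")[:K]
    votes = np.bincount(data.y[order])
    return int(np.argmax(votes))
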
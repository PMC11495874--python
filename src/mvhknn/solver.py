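r"""The multi-view robust local-hyperplane solver, MvHKNN(KRP).

For every (test sample, class) pair the solver minimizes

    LH_c(alpha) = lambda_r ||alpha||^2
                + (1/(lam d)) sum_j exp{ lam [1 - kappa(x_j - V_j alpha)]^(p/2) }
                + mu * alpha^T L*(beta) alpha

over the K reconstruction weights ``alpha``, where ``L*(beta) =
sum_v beta_v^rho L_v`` fuses the normalized Laplacians of the m
similarity views with simplex weights ``beta``. The minimization
alternates, per round,

1. fuse the Laplacians at the current ``beta``;
2. compute the half-quadratic diagonal ``Lambda`` at the current alpha;
3. solve the weighted ridge system
   ``(lambda1 I + V^T Lambda V + lambda2 L*) alpha = V^T Lambda x``
   with ``lambda1 = 4 sigma^2 d lambda_r / p`` and
   ``lambda2 = 4 sigma^2 d mu / p`` (so the linear solve is exactly the
   stationarity condition of LH_c at frozen Lambda and L*);
4. update ``beta`` in closed form from the KKT conditions of
   ``min_beta trace(alpha^T L*(beta) alpha)`` on the simplex:
   ``beta_v \propto trace(alpha^T L_v alpha)^(-1/(rho-1))``,
   so views on which alpha is already smooth gain weight.

The query is assigned to the class with the smallest final objective.
There is no training phase: the classifier is lazy and re-runs this fit
per query and class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import FeatureDataset
from .exceptions import (
    ConfigurationError,
    ContractViolationError,
    SingularSystemWarning,
)
from .graphs import NormalizedLaplacian, SimilarityView, build_view_laplacians
from .hknn import ClassNeighborhood, find_neighborhood
from .krp import KRPParams, lambda_diag, objective

__all__ = [
    "Hyperparameters",
    "SolverState",
    "fuse_laplacians",
    "update_beta",
    "update_alpha",
    "fit_sample_class",
    "classify",
    "without_graph",
]

logger = logging.getLogger(__name__)

# trace(alpha^T L alpha) at or below this is treated as exactly smooth;
# the corresponding unnormalized beta weight is capped at _TM_CAP.
_TRACE_TINY = 1e-12
_TM_CAP = 1e12


@dataclass(frozen=True)
class Hyperparameters:
    """All scalar knobs of the model.

    lambda_r : ridge weight on ||alpha||^2 (>= 0).
    krp      : KRP loss parameters (lam, sigma, p).
    mu       : weight of the fused-graph penalty (>= 0).
    rho      : fusion exponent; must exceed 1 (the beta update divides
               by rho - 1).
    gamma    : RBF similarity width; None means 1/d.
    K        : neighbourhood size per class.
    iterations : rounds of the alternating fit (the scheme is stopped
               early rather than run to convergence; 3 by default).
    views    : similarity views to fuse (m = len(views)).
    seed     : seed for the random alpha initialization.
    enforce_d_gt_K : refuse fits with d <= K (the closed-form update is
               derived under d > K); set False to demote to a warning.
    mutual_scope : pool over which neighbour mutuality is judged
               ("class" or "neighborhood").
    lambda_mode : which Lambda diagonal to use (see :mod:`mvhknn.krp`).
    alpha_tol : optional early-stopping tolerance on ||alpha_change||;
               None (default) runs all iterations.
    """

    lambda_r: float = 0.01
    krp: KRPParams = field(default_factory=KRPParams)
    mu: float = 0.01
    rho: float = 2.0
    gamma: float | None = None
    K: int = 5
    iterations: int = 3
    views: tuple[str, ...] = ("rbf", "cosine", "pearson")
    seed: int = 0
    enforce_d_gt_K: bool = True
    mutual_scope: str = "class"
    lambda_mode: str = "derivative_consistent"
    alpha_tol: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_r < 0 or self.mu < 0:
            raise ConfigurationError("lambda_r and mu must be >= 0")
        if self.rho <= 1:
            raise ConfigurationError("rho must be > 1")
        if self.K < 1 or self.iterations < 1:
            raise ConfigurationError("K and iterations must be >= 1")
        if len(self.views) < 1:
            raise ConfigurationError("at least one similarity view is required")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigurationError("gamma must be > 0")

    @property
    def m(self) -> int:
        return len(self.views)

    def similarity_views(self) -> list[SimilarityView]:
        return [SimilarityView(name=v, gamma=self.gamma) for v in self.views]

    def reparameterized(self, d: int) -> tuple[float, float]:
        """(lambda1, lambda2) of the linear solve for feature dimension d."""
        s2 = self.krp.sigma**2
        lambda1 = 4.0 * s2 * d * self.lambda_r / self.krp.p
        lambda2 = 4.0 * s2 * d * self.mu / self.krp.p
        return lambda1, lambda2


@dataclass
class SolverState:
    """Final state of one (sample, class) fit."""

    alpha: np.ndarray
    beta: np.ndarray
    L_star: np.ndarray | None
    lambda1: float
    lambda2: float
    objective_trace: list[float]
    beta_trace: list[np.ndarray] = field(default_factory=list)
    neighborhood: ClassNeighborhood | None = None


def _as_matrices(laplacians) -> list[np.ndarray]:
    out = []
    for L in laplacians:
        M = L.matrix if isinstance(L, NormalizedLaplacian) else np.asarray(L, float)
        out.append(M)
    shapes = {M.shape for M in out}
    if len(shapes) != 1 or any(M.ndim != 2 or M.shape[0] != M.shape[1] for M in out):
        raise ContractViolationError(f"Laplacians must share a square shape, got {shapes}")
    return out


def fuse_laplacians(laplacians, beta: Sequence[float], rho: float) -> np.ndarray:
    """``L* = sum_v beta_v^rho L_v`` (symmetric PSD for simplex beta)."""
    mats = _as_matrices(laplacians)
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != len(mats):
        raise ContractViolationError(
            f"{len(mats)} Laplacians but {beta.size} weights"
        )
    L = np.zeros_like(mats[0])
    for b, M in zip(beta, mats):
        L += (b**rho) * M
    return L


def update_beta(alpha: np.ndarray, laplacians, rho: float) -> np.ndarray:
    """Closed-form simplex weights from the KKT conditions.

    ``beta_v = tm_v / sum_w tm_w`` with
    ``tm_v = trace(alpha^T L_v alpha)^(-1/(rho-1))``; a vanishing trace
    (alpha perfectly smooth on that view) caps ``tm_v`` at 1e12 so the
    view dominates without producing infinities. Exactly equal traces
    return the uniform vector exactly.
    """
    if rho <= 1:
        raise ConfigurationError("rho must be > 1")
    mats = _as_matrices(laplacians)
    alpha = np.asarray(alpha, dtype=float).ravel()
    traces = np.array([float(alpha @ (M @ alpha)) for M in mats])
    traces = np.maximum(traces, 0.0)  # PSD up to rounding
    m = len(mats)
    if np.all(traces == traces[0]):
        return np.full(m, 1.0 / m)
    tm = np.where(
        traces <= _TRACE_TINY,
        _TM_CAP,
        np.power(1.0 / np.where(traces <= _TRACE_TINY, 1.0, traces), 1.0 / (rho - 1.0)),
    )
    tm = np.minimum(tm, _TM_CAP)
    beta = tm / tm.sum()
    return np.clip(beta, 0.0, 1.0)


def update_alpha(x: np.ndarray, V: np.ndarray, Lambda: np.ndarray,
                 L_star: np.ndarray | None, lambda1: float,
                 lambda2: float) -> np.ndarray:
    """One closed-form half-quadratic step:
    ``alpha = (lambda1 I + V^T Lambda V + lambda2 L*)^{-1} V^T Lambda x``."""
    x = np.asarray(x, dtype=float).ravel()
    V = np.asarray(V, dtype=float)
    Lambda = np.asarray(Lambda, dtype=float).ravel()
    if np.any(Lambda < 0):
        raise ContractViolationError("Lambda entries must be >= 0")
    K = V.shape[1]
    A = lambda1 * np.eye(K) + V.T @ (Lambda[:, None] * V)
    if lambda2 != 0.0:
        if L_star is None:
            raise ContractViolationError("lambda2 != 0 requires a fused Laplacian")
        A = A + lambda2 * np.asarray(L_star, dtype=float)
    b = V.T @ (Lambda * x)
    try:
        if lambda1 == 0.0 and np.linalg.matrix_rank(A) < K:
            raise np.linalg.LinAlgError("rank deficient")
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular weighted system; returning the least-norm solution",
            SingularSystemWarning,
        )
        return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_sample_class(x: np.ndarray, data: FeatureDataset, c: int,
                     hp: Hyperparameters) -> tuple[SolverState, float]:
    """Alternating fit of alpha, beta for one query and one class.

    Per round: fuse Laplacians -> compute Lambda -> solve for alpha ->
    update beta. The per-view Laplacians are built once, before the loop,
    from the mutual-KNN graphs of the K class-c neighbours. Fully
    deterministic given ``hp.seed``.

    Returns the final state and the final objective LH_c.
    """
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    if d <= hp.K:
        msg = (f"feature dimension d={d} must exceed K={hp.K} for the "
               f"closed-form weight update")
        if hp.enforce_d_gt_K:
            raise ConfigurationError(msg)
        warnings.warn(msg, UserWarning)

    nb = find_neighborhood(x, data, c, hp.K)
    pool = data.X[data.class_indices(c)]
    laps = build_view_laplacians(nb, pool, hp.similarity_views(), hp.K,
                                 hp.mutual_scope)
    lap_mats = [L.matrix for L in laps]

    rng = np.random.default_rng(hp.seed)
    alpha = rng.standard_normal(hp.K) / hp.K
    beta = np.full(hp.m, 1.0 / hp.m)
    lambda1, lambda2 = hp.reparameterized(d)

    use_graph = hp.mu > 0
    L0 = fuse_laplacians(lap_mats, beta, hp.rho) if use_graph else None
    trace: list[float] = [objective(x, nb.V, alpha, L0, hp.lambda_r, hp.mu, hp.krp)]
    beta_trace: list[np.ndarray] = [beta.copy()]
    for it in range(hp.iterations):
        L_star = fuse_laplacians(lap_mats, beta, hp.rho) if use_graph else None
        e = x - nb.V @ alpha
        Lam = lambda_diag(e, hp.krp, mode=hp.lambda_mode)
        alpha_new = update_alpha(x, nb.V, Lam, L_star, lambda1, lambda2)
        obj = objective(x, nb.V, alpha_new, L_star, hp.lambda_r, hp.mu, hp.krp)
        trace.append(obj)
        if use_graph and hp.m > 1:
            beta = update_beta(alpha_new, lap_mats, hp.rho)
        beta_trace.append(beta.copy())
        delta = float(np.linalg.norm(alpha_new - alpha))
        alpha = alpha_new
        if hp.alpha_tol is not None and delta <= hp.alpha_tol:
            break

    L_final = fuse_laplacians(lap_mats, beta, hp.rho) if use_graph else None
    final_obj = objective(x, nb.V, alpha, L_final, hp.lambda_r, hp.mu, hp.krp)
    logger.debug("fit class %s: objective trace %s -> %.6g", c, trace, final_obj)
    state = SolverState(alpha=alpha, beta=beta, L_star=L_final,
                        lambda1=lambda1, lambda2=lambda2,
                        objective_trace=trace, beta_trace=beta_trace,
                        neighborhood=nb)
    return state, final_obj


def classify(x: np.ndarray, data: FeatureDataset,
             hp: Hyperparameters) -> tuple[int, np.ndarray, float | None]:
    """Assign x to the class with the smallest final objective.

    Returns ``(label, per_class_objectives, score)``; objectives are
    ordered by ascending class label and ties resolve to the lowest
    label. For binary problems the ROC score is ``LH_0 - LH_1`` (larger
    means more class-1-like); for other class counts it is ``None``.
    """
    classes = data.classes
    if classes.size < 2:
        raise ConfigurationError("classification needs at least two classes")
    objs = np.empty(classes.size)
    for i, c in enumerate(classes):
        _, objs[i] = fit_sample_class(x, data, int(c), hp)
    label = int(classes[int(np.argmin(objs))])
    score = float(objs[0] - objs[1]) if classes.size == 2 else None
    return label, objs, score


def without_graph(hp: Hyperparameters) -> Hyperparameters:
    """The single-view, graph-free ablation of ``hp`` (HKNN with the KRP
    loss but no Laplacian penalty)."""
    return replace(hp, mu=0.0)
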
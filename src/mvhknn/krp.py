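r"""Kernel risk-sensitive mean p-power error (KRP).

The KRP of a residual ``e`` is the bounded, smooth loss

    J(e) = (1/lam) * exp{ lam * [1 - kappa_sigma(e)]^(p/2) }

where ``kappa_sigma(e) = exp(-e^2 / (2 sigma^2))`` is a Gaussian kernel.
Because ``kappa`` lies in (0, 1], ``J`` is bounded between ``1/lam`` and
``exp(lam)/lam``: a gross outlier can never dominate the objective the way
it does under squared error, and the derivative of ``J`` decays to zero
for large residuals, which is the robustness mechanism of the whole model.

Averaged over the d feature dimensions of one test sample and combined
with a ridge penalty and a graph penalty, the per-sample, per-class
objective minimized by the solver is

    LH_c(alpha) = lambda_r ||alpha||^2
                + (1/(lam d)) sum_j exp{ lam [1 - kappa(x_j - V_j alpha)]^(p/2) }
                + mu * alpha^T L* alpha .

Stationarity of the middle term can be written with a diagonal reweighting
matrix ``Lambda``; iterating "compute Lambda at the current alpha, solve
the resulting weighted ridge system" is a half-quadratic-style fixed-point
scheme. Differentiating gives

    Lambda_jj = exp{ lam [1-kappa]^(p/2) } * [1-kappa]^((p-2)/2) * kappa ,

the ``derivative_consistent`` mode. A variant with middle exponent
``p/2`` instead of ``(p-2)/2`` circulates in the literature and is kept
behind ``mode="as_printed"``; the two differ by a factor ``1 - kappa``,
so they agree only in the limit of vanishing residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ContractViolationError

__all__ = [
    "KRPParams",
    "gaussian_kernel",
    "krp_value",
    "lambda_diag",
    "krp_loss_term",
    "krp_loss_gradient",
    "objective",
]

# Floor applied to (1 - kappa) before a negative exponent (p < 2) so that
# an exact reconstruction does not divide by zero.
_ONE_MINUS_KAPPA_FLOOR = 1e-12

LAMBDA_MODES = ("derivative_consistent", "as_printed")


@dataclass(frozen=True)
class KRPParams:
    """Risk sensitivity ``lam`` (> 0), kernel bandwidth ``sigma`` (> 0, in
    the units of one feature coordinate), and power ``p`` (> 0)."""

    lam: float = 1.0
    sigma: float = 1.0
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ConfigurationError("KRP lam must be > 0")
        if self.sigma <= 0:
            raise ConfigurationError("KRP sigma must be > 0")
        if self.p <= 0:
            raise ConfigurationError("KRP p must be > 0")


def gaussian_kernel(e, sigma: float):
    """``exp(-e^2 / (2 sigma^2))``, elementwise; in (0, 1]."""
    if sigma <= 0:
        raise ConfigurationError("sigma must be > 0")
    e = np.asarray(e, dtype=float)
    out = np.exp(-(e * e) / (2.0 * sigma * sigma))
    return float(out) if out.ndim == 0 else out


def _one_minus_kappa(e, params: KRPParams, floor: bool):
    u = 1.0 - gaussian_kernel(e, params.sigma)
    if floor and params.p < 2:
        u = np.maximum(u, _ONE_MINUS_KAPPA_FLOOR)
    return u


def krp_value(A, B, params: KRPParams) -> float:
    """Empirical KRP between two equal-length vectors.

    ``(1/(N lam)) * sum_i exp{ lam [1 - kappa(a_i - b_i)]^(p/2) }``;
    symmetric in A, B and bounded in ``[1/lam, exp(lam)/lam]``, attaining
    the lower bound exactly when ``A == B``.
    """
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    if A.shape != B.shape:
        raise ContractViolationError(f"length mismatch: {A.size} vs {B.size}")
    if A.size == 0:
        raise ContractViolationError("empty vectors")
    u = 1.0 - gaussian_kernel(A - B, params.sigma)
    vals = np.exp(params.lam * np.power(u, params.p / 2.0))
    return float(vals.mean() / params.lam)


def lambda_diag(residuals, params: KRPParams,
                mode: str = "derivative_consistent") -> np.ndarray:
    """Diagonal of the half-quadratic reweighting matrix ``Lambda``.

    Entries are non-negative and bounded by ``exp(lam)``; they rise and
    then decay toward zero as |e| grows, which is what down-weights
    outlying feature dimensions. ``0^0`` is taken as 1 so that the p = 2,
    zero-residual case gives ``Lambda_jj = 1``.
    """
    if mode not in LAMBDA_MODES:
        raise ConfigurationError(f"unknown lambda_diag mode {mode!r}")
    e = np.asarray(residuals, dtype=float)
    kappa = gaussian_kernel(e, params.sigma)
    u = _one_minus_kappa(e, params, floor=True)
    q = (params.p - 2.0) / 2.0 if mode == "derivative_consistent" else params.p / 2.0
    with np.errstate(divide="ignore"):
        middle = np.where(q == 0.0, 1.0, np.power(u, q))
    return np.exp(params.lam * np.power(u, params.p / 2.0)) * middle * kappa


def krp_loss_term(x, V, alpha, params: KRPParams) -> float:
    """The dimension-averaged KRP reconstruction term
    ``(1/(lam d)) sum_j exp{ lam [1 - kappa(x_j - V_j alpha)]^(p/2) }``."""
    x = np.asarray(x, dtype=float).ravel()
    V = np.asarray(V, dtype=float)
    alpha = np.asarray(alpha, dtype=float).ravel()
    if V.shape != (x.size, alpha.size):
        raise ContractViolationError(
            f"V has shape {V.shape}, expected ({x.size}, {alpha.size})"
        )
    e = x - V @ alpha
    u = np.power(1.0 - gaussian_kernel(e, params.sigma), params.p / 2.0)
    return float(np.exp(params.lam * u).sum() / (params.lam * x.size))


def krp_loss_gradient(x, V, alpha, params: KRPParams,
                      mode: str = "derivative_consistent") -> np.ndarray:
    """Analytic gradient of :func:`krp_loss_term` with respect to alpha:
    ``-(p / (2 sigma^2 d)) * V^T Lambda (x - V alpha)``."""
    x = np.asarray(x, dtype=float).ravel()
    V = np.asarray(V, dtype=float)
    alpha = np.asarray(alpha, dtype=float).ravel()
    e = x - V @ alpha
    lam_diag = lambda_diag(e, params, mode=mode)
    c = params.p / (2.0 * params.sigma**2 * x.size)
    return -c * (V.T @ (lam_diag * e))


def objective(x, V, alpha, L_star, lambda_r: float, mu: float,
              params: KRPParams) -> float:
    """Full per-sample, per-class objective ``LH_c(alpha)``.

    ``L_star`` may be ``None`` when ``mu == 0``.
    """
    if lambda_r < 0 or mu < 0:
        raise ConfigurationError("lambda_r and mu must be >= 0")
    alpha = np.asarray(alpha, dtype=float).ravel()
    val = lambda_r * float(alpha @ alpha) + krp_loss_term(x, V, alpha, params)
    if mu > 0:
        if L_star is None:
            raise ContractViolationError("mu > 0 requires a fused Laplacian")
        L = np.asarray(L_star, dtype=float)
        if L.shape != (alpha.size, alpha.size):
            raise ContractViolationError(
                f"L_star has shape {L.shape}, expected ({alpha.size}, {alpha.size})"
            )
        val += mu * float(alpha @ (L @ alpha))
    return val
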
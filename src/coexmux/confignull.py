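"""Configuration model for correlation matrices.

The null model for a correlation layer is the correlation matrix that
maximizes the Gaussian differential entropy (equivalently, the
log-determinant) subject to (a) a unit diagonal and (b) each gene's strength
-- its row sum, diagonal included -- matching the input's.  The maximizer is
unique by strict concavity of log-det, and its inverse K has the stationary
form K_ij = (lambda_i + lambda_j)/2 off the diagonal with free diagonal
entries; the fit therefore solves the smooth convex dual over the 2N
Lagrange multipliers.

Sampling from the fitted null draws independent zero-mean Gaussian vectors
with the null covariance and returns their sample covariance, the C^con used
by the closed-form significance moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "NullLayer",
    "SampledCovariance",
    "ConfigModelError",
    "fit_configuration_model",
    "sample_null_covariance",
]


class ConfigModelError(RuntimeError):
    """Raised for invalid input or non-convergence of the null-model fit."""


@dataclass
class NullLayer:
    """Fitted maximum-entropy null for one correlation layer."""

    layer_name: str
    null_rho: np.ndarray
    multipliers: tuple  # (lambda, mu) length-N vectors of Lagrange parameters
    residual: float  # max absolute constraint violation
    iterations: int

    @property
    def log_det(self) -> float:
        return float(np.linalg.slogdet(self.null_rho)[1])


@dataclass
class SampledCovariance:
    """Sample covariance of n_obs Gaussian draws from a fitted null."""

    matrix: np.ndarray
    n_obs: int
    seed: int


def _validate_correlation(rho: np.ndarray, psd_tol: float) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if rho.shape != (n, n):
        raise ConfigModelError("input must be square")
    if not np.allclose(rho, rho.T, atol=1e-10):
        raise ConfigModelError("input correlation matrix is not symmetric")
    if not np.allclose(np.diag(rho), 1.0, atol=1e-8):
        raise ConfigModelError("input correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(rho)
    if w[0] < -psd_tol:
        raise ConfigModelError(
            f"input is not positive semidefinite (min eigenvalue {w[0]:.3e})"
        )
    return rho


def _ridge_lift(rho: np.ndarray, eps: float) -> np.ndarray:
    """Lift a near-singular correlation matrix and renormalize to unit diagonal."""
    n = rho.shape[0]
    lifted = rho + eps * np.eye(n)
    d = 1.0 / np.sqrt(np.diag(lifted))
    return lifted * np.outer(d, d)


def _dual_parts(theta: np.ndarray, n: int):
    """Build K(theta) = sum of constraint matrices and try a Cholesky factor."""
    lam, mu = theta[:n], theta[n:]
    k = 0.5 * (lam[:, None] + lam[None, :])
    np.fill_diagonal(k, lam + mu)
    try:
        chol = np.linalg.cholesky(k)
    except np.linalg.LinAlgError:
        return k, None
    return k, chol


def fit_configuration_model(
    rho: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    layer_name: str = "",
    psd_tol: float = 1e-8,
    ridge: float = 1e-8,
) -> NullLayer:
    """Fit the strength-preserving maximum-entropy null of a correlation matrix.

    Parameters
    ----------
    rho : ndarray, shape (N, N)
        Valid correlation matrix (symmetric, unit diagonal, PSD within
        ``psd_tol``).  Near-singular inputs are ridge-lifted by ``ridge`` on
        the diagonal and renormalized, with a logged warning.
    tol : float
        Maximum absolute constraint violation (row sums and diagonal)
        accepted at convergence.
    max_iter : int
        Iteration cap for the dual minimization.

    Returns
    -------
    NullLayer
        With ``null_rho`` symmetric, exactly unit-diagonal and positive
        definite, and ``residual`` <= ``tol``.
    """
    rho = _validate_correlation(rho, psd_tol)
    n = rho.shape[0]
    w_min = np.linalg.eigvalsh(rho)[0]
    if w_min < 1e-6:
        logger.warning(
            "layer %s: near-singular input (min eigenvalue %.3e); "
            "ridge-lifting by %.1e", layer_name, w_min, ridge,
        )
        rho = _ridge_lift(rho, ridge)
    strengths = rho.sum(axis=1)

    # Dual: g(lam, mu) = -log det K + lam . s + sum(mu); grad components are
    # exactly the constraint violations of C = K^{-1}, so the L-BFGS gradient
    # tolerance doubles as the fit tolerance.
    def objective(theta):
        k, chol = _dual_parts(theta, n)
        if chol is None:
            # Large finite penalty: lets the line search backtrack into the
            # positive-definite cone (an infinite value aborts it).
            return 1e12, np.zeros_like(theta)
        log_det_k = 2.0 * np.sum(np.log(np.diag(chol)))
        inv_chol = np.linalg.inv(chol)
        c = inv_chol.T @ inv_chol  # K^{-1}
        grad = np.concatenate([strengths - c.sum(axis=1), 1.0 - np.diag(c)])
        value = -log_det_k + lam_dot(theta)
        return value, grad

    def lam_dot(theta):
        return float(theta[:n] @ strengths + theta[n:].sum())

    theta0 = np.concatenate([np.zeros(n), np.ones(n)])  # K = I
    result = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                 "gtol": tol / 10.0, "ftol": 0.0},
    )
    theta = result.x
    k, chol = _dual_parts(theta, n)
    if chol is None:
        raise ConfigModelError("dual iterate left the positive-definite cone")
    inv_chol = np.linalg.inv(chol)
    null_rho = inv_chol.T @ inv_chol

    def _residual(c):
        return float(
            max(
                np.abs(c.sum(axis=1) - strengths).max(),
                np.abs(np.diag(c) - 1.0).max(),
            )
        )

    # Newton polish on the dual: the Hessian of -log det K has the closed
    # form H_ll = (r r^T + (1^T C 1) C) / 2, H_lm = C * r (columnwise),
    # H_mm = C**2, with r = C 1.  Quadratic convergence from the L-BFGS
    # iterate pushes the residual well below tol.
    newton_iters = 0
    for _ in range(50):
        residual = _residual(null_rho)
        if residual <= tol / 100.0:
            break
        r = null_rho.sum(axis=1)
        t = float(r.sum())
        grad = np.concatenate([strengths - r, 1.0 - np.diag(null_rho)])
        h_ll = (np.outer(r, r) + t * null_rho) / 2.0
        h_lm = null_rho * r[None, :]
        h_mm = null_rho ** 2
        hess = np.block([[h_ll, h_lm], [h_lm.T, h_mm]])
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(2 * n), grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            k_try, chol_try = _dual_parts(theta - scale * step, n)
            if chol_try is not None:
                inv_chol = np.linalg.inv(chol_try)
                c_try = inv_chol.T @ inv_chol
                if _residual(c_try) < residual:
                    theta = theta - scale * step
                    null_rho = c_try
                    break
            scale /= 2.0
        else:
            break
        newton_iters += 1
    residual = _residual(null_rho)
    if residual > tol:
        raise ConfigModelError(
            f"configuration-model fit did not reach tol={tol:g} within "
            f"{max_iter} iterations (residual {residual:.3e})"
        )
    # Final projection: exact symmetry and unit diagonal.
    null_rho = (null_rho + null_rho.T) / 2.0
    np.fill_diagonal(null_rho, 1.0)
    return NullLayer(
        layer_name=layer_name,
        null_rho=null_rho,
        multipliers=(theta[:n].copy(), theta[n:].copy()),
        residual=residual,
        iterations=int(result.nit) + newton_iters,
    )


def sample_null_covariance(null: NullLayer, n_obs: int, seed: int) -> SampledCovariance:
    """Sample covariance of ``n_obs`` iid Gaussian draws from the null.

    Uses a Cholesky factorization of ``null_rho`` and the unbiased
    (``n_obs - 1``) covariance denominator.
    """
    if n_obs < 2:
        raise ValueError("n_obs must be >= 2")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(null.null_rho)
    x = rng.standard_normal((n_obs, null.null_rho.shape[0])) @ chol.T
    x = x - x.mean(axis=0, keepdims=True)
    matrix = (x.T @ x) / (n_obs - 1)
    return SampledCovariance(matrix=matrix, n_obs=n_obs, seed=seed)
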
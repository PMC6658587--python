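"""Adaptive Gauss-Hermite quadrature for Gaussian-dominated latent integrands.

All latent integrals in this package are of the form ``exp(log_f(zeta))`` with
``log_f`` concave-dominated by a Gaussian kernel in 1 or 2 latent dimensions.
We therefore center a Gauss-Hermite product rule at the Laplace mode of the
integrand (mode plus inverse-Hessian scaling) and double the node count until
the integral stabilizes.  Everything is computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import ImproperLatentDistributionError, QuadratureConvergenceError

__all__ = [
    "GaussHermiteSpec",
    "laplace_center",
    "gh_log_integral",
    "gh_moments",
    "adaptive_log_integral",
]


@dataclass(frozen=True)
class GaussHermiteSpec:
    """Node budget and stopping rule for the adaptive product rule.

    nodes: starting nodes per latent dimension (doubled as 2n+1 per pass).
    max_doublings: refinement passes before giving up.
    rtol: relative change of the integral below which we stop.
    runaway_bound: |mode| beyond which the integrand is declared improper.
    """

    nodes: int = 61
    max_doublings: int = 3
    rtol: float = 1e-8
    runaway_bound: float = 1e3


@lru_cache(maxsize=32)
def _hermgauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, np.log(w) + x**2  # log(w_i * e^{x_i^2}), the e^{-x^2}-free weight


def _product_nodes(n: int, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product nodes (N, dim) and summed log-weights (N,)."""
    x, logw = _hermgauss(n)
    if dim == 1:
        return x[:, None], logw
    grids = np.meshgrid(*([x] * dim), indexing="ij")
    lw = np.meshgrid(*([logw] * dim), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    logws = np.sum([l.ravel() for l in lw], axis=0)
    return nodes, logws


def _numeric_hessian(log_f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.empty((k, k))
    steps = h * (1.0 + np.abs(x))
    f0 = float(log_f(x[None, :])[0])
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        fp = float(log_f((x + ei)[None, :])[0])
        fm = float(log_f((x - ei)[None, :])[0])
        H[i, i] = (fp - 2.0 * f0 + fm) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            fpp = float(log_f((x + ei + ej)[None, :])[0])
            fpm = float(log_f((x + ei - ej)[None, :])[0])
            fmp = float(log_f((x - ei + ej)[None, :])[0])
            fmm = float(log_f((x - ei - ej)[None, :])[0])
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def laplace_center(log_f, x0: np.ndarray, spec: GaussHermiteSpec | None = None):
    """Mode and local Gaussian covariance of exp(log_f).

    Raises ImproperLatentDistributionError when the optimizer runs away or the
    negative Hessian at the mode is not positive definite (the integrand is
    then not integrable by a Gaussian-dominated rule).
    """
    spec = spec or GaussHermiteSpec()
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))

    def neg(z):
        val = float(log_f(np.atleast_2d(z))[0])
        return np.inf if np.isnan(val) else -val

    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    mode = np.atleast_1d(res.x)
    if not np.all(np.isfinite(mode)) or np.linalg.norm(mode) > spec.runaway_bound:
        raise ImproperLatentDistributionError(
            "integrand mode runs away; normalizing constant Z of g is not finite "
            "(finiteness condition of the Kac-type latent distribution violated)",
            condition="0 < Z < inf",
        )
    H = _numeric_hessian(log_f, mode)
    eigvals, eigvecs = np.linalg.eigh(-H)
    if np.any(eigvals <= 0):
        raise ImproperLatentDistributionError(
            "log-integrand is not locally concave at its mode; the integral over "
            "the latent space diverges (improper g)",
            condition="negative definite Hessian at mode",
        )
    cov = (eigvecs / eigvals) @ eigvecs.T
    return mode, cov


def gh_log_integral(log_f, center: np.ndarray, cov: np.ndarray, n: int) -> float:
    """log of integral exp(log_f(zeta)) d zeta with an n-node/dim rule at center."""
    center = np.atleast_1d(np.asarray(center, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    k = center.size
    L = np.linalg.cholesky(cov)
    z, logw = _product_nodes(n, k)
    zeta = center + np.sqrt(2.0) * z @ L.T
    logf = np.asarray(log_f(zeta), dtype=float)
    const = 0.5 * k * np.log(2.0) + np.sum(np.log(np.diag(L)))
    return float(logsumexp(logw + logf) + const)


def adaptive_log_integral(log_f, x0, spec: GaussHermiteSpec | None = None,
                          center: np.ndarray | None = None,
                          cov: np.ndarray | None = None,
                          check_boundary: bool = False) -> float:
    """Laplace-centered adaptive GH integral of exp(log_f) in log space.

    ``log_f`` maps an (N, k) array of latent points to (N,) log values.
    When ``center``/``cov`` are not supplied they come from laplace_center.
    ``check_boundary`` additionally verifies the log-integrand decays at
    mode +/- 8 local SDs (a growing boundary flags an improper integrand).
    """
    spec = spec or GaussHermiteSpec()
    if center is None or cov is None:
        center, cov = laplace_center(log_f, x0, spec)
    center = np.atleast_1d(np.asarray(center, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if check_boundary:
        f_mode = float(log_f(center[None, :])[0])
        eigvals, eigvecs = np.linalg.eigh(cov)
        for j in range(center.size):
            step = 8.0 * np.sqrt(eigvals[j]) * eigvecs[:, j]
            for sgn in (-1.0, 1.0):
                f_b = float(log_f((center + sgn * step)[None, :])[0])
                if f_b >= f_mode:
                    raise ImproperLatentDistributionError(
                        "log-integrand grows along the grid boundary; the "
                        "normalizing constant Z of g diverges (improper g)",
                        condition="0 < Z < inf",
                    )
    n = spec.nodes
    prev = gh_log_integral(log_f, center, cov, n)
    for _ in range(spec.max_doublings):
        n = 2 * n + 1
        cur = gh_log_integral(log_f, center, cov, n)
        if abs(np.expm1(cur - prev)) < spec.rtol:
            return cur
        prev = cur
    raise QuadratureConvergenceError(
        f"Gauss-Hermite rule did not stabilize to rtol={spec.rtol} "
        f"within {spec.max_doublings} refinements (last n={n})"
    )


def gh_moments(log_f, x0, spec: GaussHermiteSpec | None = None):
    """Normalized mean, covariance, skewness and excess kurtosis of the
    density proportional to exp(log_f), by Laplace-centered GH quadrature.

    Returns (mean (k,), cov (k,k), skew (k,), excess_kurtosis (k,)).
    """
    spec = spec or GaussHermiteSpec()
    center, cov0 = laplace_center(log_f, x0, spec)
    k = center.size
    L = np.linalg.cholesky(cov0)

    def compute(n):
        z, logw = _product_nodes(n, k)
        zeta = center + np.sqrt(2.0) * z @ L.T
        lp = logw + np.asarray(log_f(zeta), dtype=float)
        w = np.exp(lp - logsumexp(lp))
        mean = w @ zeta
        d = zeta - mean
        covm = (w[:, None] * d).T @ d
        var = np.diag(covm)
        skew = (w @ d**3) / var**1.5
        kurt = (w @ d**4) / var**2 - 3.0
        return mean, covm, skew, kurt

    n = spec.nodes
    prev = compute(n)
    for _ in range(spec.max_doublings):
        n = 2 * n + 1
        cur = compute(n)
        if np.allclose(cur[0], prev[0], rtol=0, atol=spec.rtol * (1 + np.abs(cur[0]).max())) \
                and np.allclose(cur[1], prev[1], rtol=0, atol=spec.rtol * (1 + np.abs(cur[1]).max())):
            return cur
        prev = cur
    raise QuadratureConvergenceError(
        f"posterior moments did not stabilize within {spec.max_doublings} refinements"
    )
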
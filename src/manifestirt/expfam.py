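"""Exponential-family machinery for joint accuracy/response-time models.

A conditional model for one item is the triple (s_i, b_i, Z_i):

    p(x_i, t_i | zeta) = b_i(x_i, t_i) * exp(s_i(x_i, t_i)' zeta) / Z_i(zeta),

with a sufficient statistic s_i, a base measure b_i free of the latent
variable zeta, and a normalizer Z_i.  A curved variant covers models whose
natural parameters are functionally tied, (theta, -theta^2/2), as in the
drift diffusion model.

The latent variable is given the Kac-type distribution

    g(zeta) = (1/Z) * prod_i Z_i(zeta) * k(zeta),

with a kernel density k.  Under g the manifest (latent-integrated)
distribution of the observables has a closed form when k is normal; this
module provides that closed form, the brute-force quadrature version that
serves as its oracle, the posterior moments of zeta, and the Dutch-identity
density ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import multivariate_normal

from .errors import (
    DivergentExpectationError,
    NonFiniteNormalizerError,
    UnsupportedModelError,
)
from .quadrature import GaussHermiteSpec, adaptive_log_integral, gh_moments

__all__ = [
    "ExpFamItem",
    "CurvedExpFamItem",
    "KernelSpec",
    "LatentModel",
    "ManifestQuadratic",
    "log_g_density",
    "g_log_normalizer",
    "manifest_theorem1_log",
    "manifest_corollary1_log",
    "curved_mgf",
    "log_curved_mgf",
    "manifest_curved_log",
    "posterior_moments_closed",
    "posterior_moments_quadrature",
    "posterior_shape_quadrature",
    "dutch_identity_ratio",
]


@dataclass(frozen=True)
class ExpFamItem:
    """One item's (sufficient statistic, base measure, normalizer) triple.

    statistic(x, t) -> (k,) array; base_measure_log(x, t) -> float;
    log_normalizer(zeta (k,)) -> float.  ``log_normalizer_batch`` optionally
    accepts an (N, k) array for vectorized grid work; a row loop is used when
    it is absent.  ``time_support`` is (lower, upper); upper may be inf.
    """

    statistic: Callable[[int, float], np.ndarray]
    base_measure_log: Callable[[int, float], float]
    log_normalizer: Callable[[np.ndarray], float]
    time_support: tuple[float, float]
    dim: int
    log_normalizer_batch: Callable[[np.ndarray], np.ndarray] | None = None

    def log_normalizer_at(self, zetas: np.ndarray) -> np.ndarray:
        """Vectorized log Z_i over an (N, k) array of latent points."""
        zetas = np.atleast_2d(zetas)
        if self.log_normalizer_batch is not None:
            return np.asarray(self.log_normalizer_batch(zetas), dtype=float)
        return np.array([self.log_normalizer(z) for z in zetas], dtype=float)


@dataclass(frozen=True)
class CurvedExpFamItem:
    """Curved-family item: statistic returns (s_i1, s_i2) paired with
    natural parameters (theta, -theta^2/2); the latent dimension is 1."""

    statistic: Callable[[int, float], np.ndarray]  # -> (2,) = (s_i1, s_i2)
    base_measure_log: Callable[[int, float], float]
    log_normalizer: Callable[[float], float]  # scalar theta -> log Z_i(theta)
    time_support: tuple[float, float]
    log_normalizer_batch: Callable[[np.ndarray], np.ndarray] | None = None
    dim: int = 1

    def log_normalizer_at(self, zetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(zetas)[:, 0]
        if self.log_normalizer_batch is not None:
            return np.asarray(self.log_normalizer_batch(thetas), dtype=float)
        return np.array([self.log_normalizer(th) for th in thetas], dtype=float)


@dataclass(frozen=True)
class KernelSpec:
    """Normal kernel k(zeta) of the latent distribution g: mean m, covariance V."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if cov.shape != (mean.size, mean.size):
            raise ValueError("kernel covariance shape does not match mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("kernel covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("kernel covariance must be positive definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def dim(self) -> int:
        return self.mean.size

    def logpdf(self, zetas: np.ndarray) -> np.ndarray:
        zetas = np.atleast_2d(zetas)
        return multivariate_normal.logpdf(zetas, mean=self.mean, cov=self.cov)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mean, self.cov, size=n)


@dataclass(frozen=True)
class LatentModel:
    """A homogeneous set of items plus the latent kernel."""

    items: tuple
    kernel: KernelSpec
    latent_dim: int

    def __post_init__(self):
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if items:
            kinds = {type(it) for it in items}
            if len(kinds) > 1:
                raise ValueError("items must be homogeneous (all plain or all curved)")
            if any(it.dim != self.latent_dim for it in items):
                raise ValueError("item statistic dimension must equal latent_dim")
        if self.kernel.dim != self.latent_dim:
            raise ValueError("kernel dimension must equal latent_dim")
        if self.curved and self.latent_dim != 1:
            raise ValueError("curved models have a scalar latent trait")

    @property
    def curved(self) -> bool:
        return bool(self.items) and isinstance(self.items[0], CurvedExpFamItem)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def total_statistic(self, x: Sequence[int], t: Sequence[float]) -> np.ndarray:
        """S = sum_i s_i(x_i, t_i); for curved items the (s_1+, s_2+) pair."""
        dim = 2 if self.curved else self.latent_dim
        S = np.zeros(dim)
        for item, xi, ti in zip(self.items, x, t):
            S += np.asarray(item.statistic(int(xi), float(ti)), dtype=float)
        return S

    def total_base_measure_log(self, x, t) -> float:
        return float(sum(it.base_measure_log(int(xi), float(ti))
                         for it, xi, ti in zip(self.items, x, t)))

    def check_support(self, t) -> None:
        for i, (item, ti) in enumerate(zip(self.items, t)):
            lo, hi = item.time_support
            if not (lo < ti < hi):
                raise ValueError(
                    f"time t[{i}]={ti} outside item support ({lo}, {hi})")

    def log_conditional(self, x, t, zeta: np.ndarray) -> float:
        """log p(x, t | zeta) reconstructed from (s_i, b_i, Z_i)."""
        zeta = np.atleast_1d(np.asarray(zeta, dtype=float))
        S = self.total_statistic(x, t)
        if self.curved:
            theta = zeta[0]
            nat = S[0] * theta - 0.5 * S[1] * theta**2
        else:
            nat = float(S @ zeta)
        logZ = float(np.sum(self._log_normalizers(zeta[None, :])))
        return self.total_base_measure_log(x, t) + nat - logZ

    def _log_normalizers(self, zetas: np.ndarray) -> np.ndarray:
        """(n_items, N) matrix of log Z_i over latent points, with finiteness check."""
        out = np.empty((self.n_items, np.atleast_2d(zetas).shape[0]))
        for i, item in enumerate(self.items):
            vals = item.log_normalizer_at(zetas)
            if np.any(np.isnan(vals)):
                raise NonFiniteNormalizerError(
                    f"normalizer Z of item {i} is non-finite (NaN) at a latent "
                    "point", item_index=i)
            out[i] = vals
        return out

    def log_g_unnormalized(self, zetas: np.ndarray) -> np.ndarray:
        """log[prod_i Z_i(zeta) k(zeta)] over an (N, k) array.

        Overflow of a Z_i far from the kernel (log Z_i = +inf) is allowed to
        propagate: the mode-runaway detector in the quadrature layer turns it
        into an improper-g error when it actually dominates.
        """
        zetas = np.atleast_2d(zetas)
        with np.errstate(over="ignore"):
            logk = self.kernel.logpdf(zetas)
            if not self.items:
                return np.atleast_1d(logk)
            return np.atleast_1d(logk) + self._log_normalizers(zetas).sum(axis=0)


@dataclass(frozen=True)
class ManifestQuadratic:
    """Quadratic manifest law  p(q) = exp(q'mu + h(q) q'Sigma q) omega(q) / Z.

    ``weight`` is the scalar h(q) (None means h == 1); ``base_measure_log``
    is log omega(q) (None means omega == 1).  ``variable_layout`` documents
    what the observation vector q stacks (e.g. "x then log-t").
    """

    intercepts: np.ndarray
    interactions: np.ndarray
    variable_layout: str
    weight: Callable[[np.ndarray], float] | None = None
    base_measure_log: Callable[[np.ndarray], float] | None = None

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        S = np.atleast_2d(np.asarray(self.interactions, dtype=float))
        if not np.allclose(S, S.T):
            raise ValueError("interaction matrix must be symmetric")
        if S.shape != (mu.size, mu.size):
            raise ValueError("interaction matrix shape does not match intercepts")
        object.__setattr__(self, "intercepts", mu)
        object.__setattr__(self, "interactions", S)

    def log_density(self, q: np.ndarray) -> float:
        """Unnormalized log density at the observation vector q."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        h = 1.0 if self.weight is None else float(self.weight(q))
        val = float(q @ self.intercepts) + h * float(q @ self.interactions @ q)
        if self.base_measure_log is not None:
            val += float(self.base_measure_log(q))
        return val

    def interaction_rank(self, tol: float = 1e-10) -> int:
        return int(np.linalg.matrix_rank(self.interactions, tol=tol))


# ---------------------------------------------------------------------------
# Latent distribution g and the manifest-distribution theorems
# ---------------------------------------------------------------------------

def g_log_normalizer(model: LatentModel, grid: GaussHermiteSpec | None = None) -> float:
    """log Z = log integral of prod_i Z_i(zeta) k(zeta) d zeta.

    Deterministic Laplace-centered Gauss-Hermite quadrature.  Raises
    ImproperLatentDistributionError when the integrand diverges (mode
    runaway, non-concavity at the mode, or growth at the grid boundary).
    """
    if not model.items:
        return 0.0
    return adaptive_log_integral(
        model.log_g_unnormalized, model.kernel.mean, grid, check_boundary=True
    )


def log_g_density(model: LatentModel, zeta: np.ndarray, normalized: bool = False,
                  grid: GaussHermiteSpec | None = None) -> float:
    """log g(zeta), unnormalized by default (Z computed on demand)."""
    val = float(model.log_g_unnormalized(np.atleast_2d(zeta))[0])
    if normalized:
        val -= g_log_normalizer(model, grid)
    return val


def manifest_theorem1_log(model: LatentModel, x, t,
                          grid: GaussHermiteSpec | None = None) -> float:
    """Unnormalized log manifest density by brute-force latent quadrature.

    Returns log[prod_i b_i * E_k(exp(S' zeta))] with the expectation over the
    kernel computed numerically.  This is the oracle against which all closed
    forms are checked; it accepts any kernel the quadrature can cover.
    """
    model.check_support(t)
    logb = model.total_base_measure_log(x, t)
    S = model.total_statistic(x, t)
    if model.curved:
        def log_f(zetas):
            th = np.atleast_2d(zetas)[:, 0]
            return S[0] * th - 0.5 * S[1] * th**2 + model.kernel.logpdf(zetas)
    else:
        def log_f(zetas):
            zetas = np.atleast_2d(zetas)
            return zetas @ S + model.kernel.logpdf(zetas)
    return logb + adaptive_log_integral(log_f, model.kernel.mean, grid)


def manifest_corollary1_log(model: LatentModel, x, t) -> float:
    """Closed-form unnormalized log manifest density for a normal kernel:

        sum_i log b_i + S'm + S'V S / 2,   S = sum_i s_i(x_i, t_i).
    """
    if model.curved:
        raise UnsupportedModelError(
            "closed form S'm + S'VS/2 requires plain exponential-family items; "
            "use manifest_curved_log for curved (drift diffusion) models")
    model.check_support(t)
    S = model.total_statistic(x, t)
    m, V = model.kernel.mean, model.kernel.cov
    return model.total_base_measure_log(x, t) + float(S @ m) + 0.5 * float(S @ V @ S)


def log_curved_mgf(r1: float, r2: float, m: float, v2: float) -> float:
    """log E[exp(r1*theta - r2*theta^2/2)] for theta ~ Normal(m, v2).

    Equal to -log(r2 v^2 + 1)/2 + (r1^2 v^2 + 2 r1 m - r2 m^2)/(2 r2 v^2 + 2);
    the r2 = 0 branch is the ordinary normal MGF.  Diverges when
    r2 v^2 + 1 <= 0.
    """
    denom = r2 * v2 + 1.0
    if denom <= 0:
        raise DivergentExpectationError(
            f"E[exp(r1*theta - r2*theta^2/2)] diverges: r2*v^2 + 1 = {denom} <= 0")
    return -0.5 * np.log(denom) + (r1**2 * v2 + 2.0 * r1 * m - r2 * m**2) / (2.0 * denom)


def curved_mgf(r1: float, r2: float, m: float, v2: float) -> float:
    """E[exp(r1*theta - r2*theta^2/2)] under theta ~ Normal(m, v2)."""
    return float(np.exp(log_curved_mgf(r1, r2, m, v2)))


def manifest_curved_log(model: LatentModel, x, t) -> float:
    """Closed-form unnormalized log manifest density for curved items:

        sum_i log b_i + log E[exp(s_1+ theta - s_2+ theta^2 / 2)],

    with the expectation under the scalar normal kernel.
    """
    if not model.curved:
        raise UnsupportedModelError(
            "manifest_curved_log applies to curved items; use "
            "manifest_corollary1_log for plain exponential-family items")
    model.check_support(t)
    S = model.total_statistic(x, t)
    m = float(model.kernel.mean[0])
    v2 = float(model.kernel.cov[0, 0])
    return model.total_base_measure_log(x, t) + log_curved_mgf(S[0], S[1], m, v2)


# ---------------------------------------------------------------------------
# Posterior of the latent variable under g
# ---------------------------------------------------------------------------

def posterior_moments_closed(model: LatentModel, x, t):
    """Posterior mean m + V S and covariance V of zeta given the data, under g
    with a normal kernel.  Exact for plain exponential-family items."""
    if model.curved:
        raise UnsupportedModelError(
            "the posterior of theta is not normal for curved items; "
            "use posterior_moments_quadrature")
    S = model.total_statistic(x, t)
    m, V = model.kernel.mean, model.kernel.cov
    return m + V @ S, V.copy()


def _log_posterior_factory(model: LatentModel, x, t):
    """Unnormalized log posterior of zeta: prop to p(x,t|zeta) g(zeta); the
    normalizers Z_i cancel, leaving exp(S' zeta) k(zeta) (curved analogue)."""
    S = model.total_statistic(x, t)
    if model.curved:
        def log_f(zetas):
            th = np.atleast_2d(zetas)[:, 0]
            return S[0] * th - 0.5 * S[1] * th**2 + model.kernel.logpdf(zetas)
    else:
        def log_f(zetas):
            return np.atleast_2d(zetas) @ S + model.kernel.logpdf(zetas)
    return log_f


def posterior_moments_quadrature(model: LatentModel, x, t,
                                 grid: GaussHermiteSpec | None = None):
    """Numeric posterior mean and covariance of zeta given (x, t)."""
    mean, cov, _, _ = gh_moments(_log_posterior_factory(model, x, t),
                                 model.kernel.mean, grid)
    return mean, cov


def posterior_shape_quadrature(model: LatentModel, x, t,
                               grid: GaussHermiteSpec | None = None):
    """Per-dimension posterior skewness and excess kurtosis (normality check)."""
    _, _, skew, kurt = gh_moments(_log_posterior_factory(model, x, t),
                                  model.kernel.mean, grid)
    return skew, kurt


# ---------------------------------------------------------------------------
# Dutch identity
# ---------------------------------------------------------------------------

def dutch_identity_ratio(model: LatentModel, x, t, y, w, mode: str = "closed",
                         grid: GaussHermiteSpec | None = None,
                         log_prior: Callable[[np.ndarray], np.ndarray] | None = None,
                         ) -> float:
    """Manifest density ratio p(x, t) / p(y, w).

    mode="closed": difference of closed-form log manifest densities.
    mode="posterior-quadrature": prod_i b_i(x,t)/b_i(y,w) times the posterior
    expectation E[exp((S(x,t) - S(y,w))' zeta) | data (y, w)] computed by
    quadrature under the posterior prop to p(y, w | zeta) * f(zeta); f
    defaults to the (unnormalized) latent distribution g.  The two modes
    agree when f = g.
    """
    if mode == "closed":
        closed = manifest_curved_log if model.curved else manifest_corollary1_log
        return float(np.exp(closed(model, x, t) - closed(model, y, w)))
    if mode != "posterior-quadrature":
        raise ValueError("mode must be 'closed' or 'posterior-quadrature'")

    model.check_support(t)
    model.check_support(w)
    Sx = model.total_statistic(x, t)
    Sy = model.total_statistic(y, w)
    if log_prior is None:
        log_prior = model.log_g_unnormalized

    def log_post(zetas):
        zetas = np.atleast_2d(zetas)
        logZ = model._log_normalizers(zetas).sum(axis=0)
        if model.curved:
            th = zetas[:, 0]
            nat = Sy[0] * th - 0.5 * Sy[1] * th**2
        else:
            nat = zetas @ Sy
        return nat - logZ + np.atleast_1d(log_prior(zetas))

    if model.curved:
        def log_num(zetas):
            th = np.atleast_2d(zetas)[:, 0]
            d = (Sx[0] - Sy[0]) * th - 0.5 * (Sx[1] - Sy[1]) * th**2
            return d + log_post(zetas)
    else:
        dS = Sx - Sy

        def log_num(zetas):
            return np.atleast_2d(zetas) @ dS + log_post(zetas)

    log_den = adaptive_log_integral(log_post, model.kernel.mean, grid)
    if not np.isfinite(log_den):
        raise ZeroDivisionError("denominator manifest density is zero at (y, w)")
    log_num_val = adaptive_log_integral(log_num, model.kernel.mean, grid)
    logb = model.total_base_measure_log(x, t) - model.total_base_measure_log(y, w)
    return float(np.exp(logb + log_num_val - log_den))
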
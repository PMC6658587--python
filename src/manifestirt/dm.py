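"""Unbiased drift diffusion model (DM) and its total-time-weighted manifest law.

Evidence accumulates as a Wiener process with drift theta + beta_i, unit
volatility, boundary separation alpha_i and unbiased start z = alpha_i / 2;
crossing the upper/lower boundary gives the correct/incorrect response and
the decision time t_i - T_er.  The joint density of accuracy and time is

    p(x_i, t_i | theta) = (pi / alpha_i^2)
        exp(alpha_i (2x_i - 1)(theta + beta_i)/2 - (t_i - T_er)(theta + beta_i)^2/2)
        * sum_{n odd} n (-1)^{(n-1)/2} exp(-pi^2 n^2 (t_i - T_er) / (2 alpha_i^2)),

the large-time series of the first-passage density for the unbiased process.
The accuracy marginal is a 2PL with discrimination alpha_i.  The model is a
curved exponential family: s_i1 = alpha_i x_i - beta_i t_i is sufficient for
theta, s_i2 = t_i for -theta^2/2.  Under a standard-normal kernel the
manifest law is quadratic in q = (x, t) with a rank-one interaction matrix
whose weight 1/(t_+ + 1) shrinks with the total time spent on the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import SeriesConvergenceError
from .expfam import CurvedExpFamItem, KernelSpec, LatentModel, ManifestQuadratic

__all__ = [
    "DMItem",
    "SeriesSpec",
    "wiener_series_factor",
    "wiener_series_factor_vec",
    "dm_joint_logdensity",
    "dm_accuracy_marginal",
    "dm_time_marginal_logdensity",
    "dm_curved_decomposition",
    "dm_manifest_params",
    "dm_manifest_logdensity",
]


@dataclass(frozen=True)
class DMItem:
    """Boundary separation alpha > 0, drift easiness beta (drift is
    theta + beta), non-decision time t_er >= 0 (seconds).  Volatility is
    fixed at 1 and the start point is unbiased (z = alpha/2)."""

    alpha: float
    beta: float
    t_er: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("boundary separation alpha must be positive")
        if self.t_er < 0:
            raise ValueError("non-decision time t_er must be nonnegative")


@dataclass(frozen=True)
class SeriesSpec:
    """Truncation control for the first-passage series."""

    tolerance: float = 1e-12
    max_terms: int = 800

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


_DEFAULT_SERIES = SeriesSpec()


# Below c = pi^2 tau / (2 alpha^2) ~ 0.0171 the series value is ~exp(-36) of
# its leading term and drowns in alternating-sum cancellation; the density
# there is below double-precision resolution and is reported as exactly zero.
_C_FLOOR = 0.0171


def _series_scalar(tau: float, alpha: float, spec: SeriesSpec):
    """sum over odd n of n (-1)^{(n-1)/2} exp(-pi^2 n^2 tau / (2 alpha^2)).

    Even n contribute nothing (sin(pi n / 2) = 0).  Truncates when the next
    term is below tolerance and the magnitudes have started to decrease, so
    the alternating-series bound applies; returns (value, bound, n_terms).
    """
    c = np.pi**2 * tau / (2.0 * alpha**2)
    if c < _C_FLOOR:
        return 0.0, 0.0, 0
    total = 0.0
    sign = 1.0
    n = 1
    terms = 0
    while True:
        mag = n * np.exp(-c * n**2)
        total += sign * mag
        terms += 1
        n_next = n + 2
        next_mag = n_next * np.exp(-c * n_next**2)
        if next_mag < spec.tolerance and next_mag <= mag:
            return max(total, 0.0), next_mag, terms
        if terms >= spec.max_terms:
            raise SeriesConvergenceError(
                f"first-passage series did not converge in {spec.max_terms} terms "
                f"(t - T_er = {tau} is too small relative to alpha^2 = {alpha**2}; "
                "the large-time representation needs a larger decision time)")
        sign = -sign
        n = n_next


def wiener_series_factor(t: float, item: DMItem, spec: SeriesSpec | None = None,
                         with_bound: bool = False):
    """Dimensionless series factor of the first-passage density at time t."""
    spec = spec or _DEFAULT_SERIES
    tau = t - item.t_er
    if tau <= 0:
        raise ValueError("t must exceed the non-decision time T_er")
    value, bound, terms = _series_scalar(tau, item.alpha, spec)
    if with_bound:
        return value, bound, terms
    return value


def wiener_series_factor_vec(tau: np.ndarray, alpha: float,
                             spec: SeriesSpec | None = None) -> np.ndarray:
    """Vectorized series over an array of decision times tau = t - T_er > 0."""
    spec = spec or _DEFAULT_SERIES
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("all decision times must be positive")
    c = np.pi**2 * tau / (2.0 * alpha**2)
    active = c >= _C_FLOOR
    total = np.zeros_like(c)
    sign = 1.0
    n = 1
    for _ in range(spec.max_terms):
        mag = n * np.exp(-c * n**2)
        total += sign * mag
        n_next = n + 2
        next_mag = n_next * np.exp(-c * n_next**2)
        if np.all(((next_mag < spec.tolerance) & (next_mag <= mag)) | ~active):
            return np.where(active, np.maximum(total, 0.0), 0.0)
        sign = -sign
        n = n_next
    raise SeriesConvergenceError(
        f"first-passage series did not converge in {spec.max_terms} terms "
        f"(smallest decision time {tau.min()} too small for alpha^2 = {alpha**2})")


def dm_joint_logdensity(x, t, theta: float, items: Sequence[DMItem],
                        spec: SeriesSpec | None = None) -> float:
    """log p(x, t | theta); -inf when any t_i <= T_er (outside the support)."""
    spec = spec or _DEFAULT_SERIES
    x = np.atleast_1d(np.asarray(x))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = 0.0
    for xi, ti, it in zip(x, t, items):
        tau = ti - it.t_er
        if tau <= 0:
            return -np.inf
        lam = theta + it.beta
        series, _, _ = _series_scalar(tau, it.alpha, spec)
        if series <= 0.0:
            return -np.inf
        out += (np.log(np.pi) - 2.0 * np.log(it.alpha)
                + 0.5 * it.alpha * (2.0 * xi - 1.0) * lam
                - 0.5 * tau * lam**2 + np.log(series))
    return float(out)


def dm_accuracy_marginal(x: int, theta: float, item: DMItem) -> float:
    """P(x | theta): 2PL with discrimination equal to the boundary
    separation alpha and easiness beta."""
    z = item.alpha * (theta + item.beta)
    return float(expit(z if x == 1 else -z))


def _log_cosh(z: float) -> float:
    z = abs(z)
    return z + np.log1p(np.exp(-2.0 * z)) - np.log(2.0)


def dm_time_marginal_logdensity(t: float, theta: float, item: DMItem,
                                spec: SeriesSpec | None = None) -> float:
    """log p(t | theta) for one item (accuracy summed out, cosh form)."""
    spec = spec or _DEFAULT_SERIES
    tau = t - item.t_er
    if tau <= 0:
        return -np.inf
    lam = theta + item.beta
    series, _, _ = _series_scalar(tau, item.alpha, spec)
    if series <= 0.0:
        return -np.inf
    return float(np.log(2.0 * np.pi) - 2.0 * np.log(item.alpha)
                 + _log_cosh(0.5 * item.alpha * lam)
                 - 0.5 * tau * lam**2 + np.log(series))


def _dm_item_to_curved(item: DMItem, spec: SeriesSpec) -> CurvedExpFamItem:
    a, b, ter = item.alpha, item.beta, item.t_er

    def statistic(x, t, a=a, b=b):
        return np.array([a * x - b * t, t])

    def base_measure_log(x, t, a=a, b=b, ter=ter, spec=spec):
        series, _, _ = _series_scalar(t - ter, a, spec)
        if series <= 0.0:
            return -np.inf
        return a * b * x - 0.5 * b**2 * t + np.log(series)

    def log_normalizer(theta, a=a, b=b, ter=ter):
        lam = float(theta) + b
        return 2.0 * np.log(a) - np.log(np.pi) + 0.5 * a * lam - 0.5 * ter * lam**2

    def log_normalizer_batch(thetas, a=a, b=b, ter=ter):
        lam = np.asarray(thetas, dtype=float) + b
        return 2.0 * np.log(a) - np.log(np.pi) + 0.5 * a * lam - 0.5 * ter * lam**2

    return CurvedExpFamItem(statistic=statistic, base_measure_log=base_measure_log,
                            log_normalizer=log_normalizer,
                            log_normalizer_batch=log_normalizer_batch,
                            time_support=(ter, np.inf))


def dm_curved_decomposition(items: Sequence[DMItem],
                            kernel: KernelSpec | None = None,
                            spec: SeriesSpec | None = None) -> LatentModel:
    """Curved-family form: s_i1 = alpha x - beta t sufficient for theta,
    s_i2 = t sufficient for -theta^2/2, base measure
    exp(alpha beta x - beta^2 t / 2) * series, and normalizer
    Z_i(theta) = (alpha^2/pi) exp(alpha lam / 2 - T_er lam^2 / 2)."""
    spec = spec or _DEFAULT_SERIES
    kernel = kernel or KernelSpec(mean=np.zeros(1), cov=np.eye(1))
    return LatentModel(items=tuple(_dm_item_to_curved(it, spec) for it in items),
                       kernel=kernel, latent_dim=1)


def dm_manifest_params(items: Sequence[DMItem],
                       kernel: KernelSpec | None = None,
                       spec: SeriesSpec | None = None) -> ManifestQuadratic:
    """Manifest quadratic over q = (x, t) under a zero-mean scalar normal
    kernel (default variance 1): intercepts (alpha*beta, -beta^2/2), rank-one
    interactions (v^2/2)(alpha, -beta)(alpha, -beta)', weight
    h(t) = v^2-scaled 1/(t_+ v^2 + 1), and base measure
    (t_+ v^2 + 1)^{-1/2} prod_i series_i."""
    spec = spec or _DEFAULT_SERIES
    kernel = kernel or KernelSpec(mean=np.zeros(1), cov=np.eye(1))
    if kernel.dim != 1:
        raise ValueError("the DM has a scalar latent trait")
    if kernel.mean[0] != 0.0:
        raise ValueError("the quadratic manifest form assumes a zero-mean kernel; "
                         "use manifest_curved_log for a general mean")
    v2 = float(kernel.cov[0, 0])
    a = np.array([it.alpha for it in items], dtype=float)
    b = np.array([it.beta for it in items], dtype=float)
    p = len(items)
    mu = np.concatenate([a * b, -0.5 * b**2])
    f = np.concatenate([a, -b])
    sigma = 0.5 * np.outer(f, f)

    def weight(q, p=p, v2=v2):
        t_plus = float(np.sum(q[p:]))
        return v2 / (t_plus * v2 + 1.0)

    def base_measure_log(q, items=items, p=p, v2=v2, spec=spec):
        t = q[p:]
        t_plus = float(np.sum(t))
        out = -0.5 * np.log(t_plus * v2 + 1.0)
        for ti, it in zip(t, items):
            series, _, _ = _series_scalar(ti - it.t_er, it.alpha, spec)
            if series <= 0.0:
                return -np.inf
            out += np.log(series)
        return out

    return ManifestQuadratic(intercepts=mu, interactions=sigma,
                             variable_layout="x then t",
                             weight=weight, base_measure_log=base_measure_log)


def dm_manifest_logdensity(x, t, items: Sequence[DMItem],
                           kernel: KernelSpec | None = None,
                           spec: SeriesSpec | None = None) -> float:
    """Unnormalized log manifest density of (x, t) via the explicit quadratic
    form; identical to the curved-family moment identity route."""
    params = dm_manifest_params(items, kernel, spec)
    for ti, it in zip(np.atleast_1d(t), items):
        if ti <= it.t_er:
            raise ValueError(f"t={ti} at or below the non-decision time {it.t_er}")
    q = np.concatenate([np.asarray(x, dtype=float), np.asarray(t, dtype=float)])
    return params.log_density(q)
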
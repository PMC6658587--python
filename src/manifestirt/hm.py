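"""Hierarchical model: 2PL accuracies, lognormal response times, bivariate-
normal latent kernel, and its quadratic manifest distribution.

The conditional model factorizes as p(x, t | theta, eta) = p(x | theta)
p(t | eta): a two-parameter logistic model with discrimination alpha_i and
easiness beta_i for accuracy, and a lognormal with time intensity xi_i and
precision phi_i for the response time, driven by ability theta and speed eta.
With a bivariate normal kernel (means 0, ability variance 1, speed variance
v_eta^2, correlation rho) the manifest distribution of accuracies and
log-times u = ln t is quadratic with a rank-two interaction matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, log_expit, logsumexp

from .expfam import ExpFamItem, KernelSpec, LatentModel, ManifestQuadratic

__all__ = [
    "HMItem",
    "HMKernel",
    "twopl_pmf",
    "lognormal_rt_logpdf",
    "hm_expfam_decomposition",
    "hm_manifest_params",
    "hm_manifest_logdensity",
    "hm_normalizability",
    "NormalizabilityReport",
    "hm_speed_variance_share",
    "hm_speed_variance_share_supremum",
    "hm_ci_conditions",
    "hm_manifest_u_normalization_trace",
]


@dataclass(frozen=True)
class HMItem:
    """discrimination alpha > 0 (0 allowed as a degenerate diagnostic case),
    easiness beta, log-time precision phi > 0, time intensity xi (log-s)."""

    alpha: float
    beta: float
    phi: float
    xi: float

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("discrimination alpha must be nonnegative")
        if self.phi <= 0:
            raise ValueError("precision phi must be positive")


@dataclass(frozen=True)
class HMKernel:
    """A-priori correlation rho of ability and speed, and speed variance
    v_eta2; ability mean/variance are fixed at 0/1 for identification."""

    rho: float
    v_eta2: float

    def __post_init__(self):
        # |rho| = 1 is allowed as a degenerate diagnostic case; the implied
        # kernel covariance is then singular and only the manifest quadratic
        # (not the latent decomposition) is available.
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.v_eta2 <= 0:
            raise ValueError("v_eta2 must be positive")

    @property
    def v_eta(self) -> float:
        return float(np.sqrt(self.v_eta2))

    def to_kernel_spec(self) -> KernelSpec:
        v = self.v_eta
        return KernelSpec(mean=np.zeros(2),
                          cov=np.array([[1.0, self.rho * v],
                                        [self.rho * v, self.v_eta2]]))


def twopl_pmf(x: int, theta: float, item: HMItem) -> float:
    """Two-parameter logistic pmf exp(x a(th+b)) / (1 + exp(a(th+b))),
    computed through the logistic CDF for stability at large |a(th+b)|."""
    z = item.alpha * (theta + item.beta)
    return float(expit(z if x == 1 else -z))


def twopl_log_pmf(x: int, theta: float, item: HMItem) -> float:
    z = item.alpha * (theta + item.beta)
    return float(log_expit(z if x == 1 else -z))


def lognormal_rt_logpdf(t: float, eta: float, item: HMItem) -> float:
    """log of sqrt(phi/2pi) (1/t) exp(-phi (ln t + eta - xi)^2 / 2)."""
    if t <= 0:
        raise ValueError("response time must be positive")
    u = np.log(t)
    return float(0.5 * np.log(item.phi / (2 * np.pi)) - u
                 - 0.5 * item.phi * (u + eta - item.xi) ** 2)


def _hm_item_to_expfam(item: HMItem) -> ExpFamItem:
    a, b, phi, xi = item.alpha, item.beta, item.phi, item.xi

    def statistic(x, t, a=a, phi=phi):
        return np.array([x * a, -phi * np.log(t)])

    def base_measure_log(x, t, a=a, b=b, phi=phi, xi=xi):
        u = np.log(t)
        return x * a * b - 0.5 * phi * u**2 - u * (1.0 - phi * xi)

    def log_normalizer(zeta, a=a, b=b, phi=phi, xi=xi):
        theta, eta = float(zeta[0]), float(zeta[1])
        return (0.5 * np.log(2 * np.pi / phi) + 0.5 * phi * (eta - xi) ** 2
                + np.logaddexp(0.0, a * (theta + b)))

    def log_normalizer_batch(zetas, a=a, b=b, phi=phi, xi=xi):
        theta, eta = zetas[:, 0], zetas[:, 1]
        return (0.5 * np.log(2 * np.pi / phi) + 0.5 * phi * (eta - xi) ** 2
                + np.logaddexp(0.0, a * (theta + b)))

    return ExpFamItem(statistic=statistic, base_measure_log=base_measure_log,
                      log_normalizer=log_normalizer,
                      log_normalizer_batch=log_normalizer_batch,
                      time_support=(0.0, np.inf), dim=2)


def hm_expfam_decomposition(items: Sequence[HMItem], kernel: HMKernel) -> LatentModel:
    """Exponential-family form of the HM with statistic s_i = (x_i alpha_i,
    -phi_i ln t_i), base measure b_i = exp(x a b - phi u^2/2 - u(1 - phi xi))
    and normalizer Z_i = sqrt(2 pi / phi) exp(phi (eta - xi)^2 / 2)
    (1 + exp(a(theta + b))); the reconstruction equals 2PL x lognormal."""
    return LatentModel(items=tuple(_hm_item_to_expfam(it) for it in items),
                       kernel=kernel.to_kernel_spec(), latent_dim=2)


def hm_manifest_params(items: Sequence[HMItem], kernel: HMKernel) -> ManifestQuadratic:
    """Quadratic manifest law over q = (x, u), u = ln t: intercepts
    (alpha*beta, phi*xi), interactions (1/2) C M C' with C = blockdiag
    columns (alpha, v phi) and M = [[1, -rho], [-rho, 1]] (rank two for
    generic parameters), and normal base measure prod exp(-phi_i u_i^2 / 2)."""
    a = np.array([it.alpha for it in items], dtype=float)
    b = np.array([it.beta for it in items], dtype=float)
    phi = np.array([it.phi for it in items], dtype=float)
    xi = np.array([it.xi for it in items], dtype=float)
    p = len(items)
    v = kernel.v_eta

    mu = np.concatenate([a * b, phi * xi])
    C = np.zeros((2 * p, 2))
    C[:p, 0] = a
    C[p:, 1] = v * phi
    M = np.array([[1.0, -kernel.rho], [-kernel.rho, 1.0]])
    sigma = 0.5 * C @ M @ C.T

    def base_measure_log(q, phi=phi, p=p):
        u = q[p:]
        return -0.5 * float(phi @ (u**2))

    return ManifestQuadratic(intercepts=mu, interactions=sigma,
                             variable_layout="x then log-t",
                             base_measure_log=base_measure_log)


def hm_manifest_logdensity(items: Sequence[HMItem], kernel: HMKernel,
                           x, u) -> float:
    """Unnormalized log manifest density of (x, u = ln t)."""
    params = hm_manifest_params(items, kernel)
    q = np.concatenate([np.asarray(x, dtype=float), np.asarray(u, dtype=float)])
    return params.log_density(q)


@dataclass(frozen=True)
class NormalizabilityReport:
    """min_rule_criterion: v_eta^2 < min_i(1/phi_i) (the stated restriction).
    exact_criterion: diag(phi) - v^2 phi phi' positive definite, equivalently
    v_eta^2 * sum_i phi_i < 1, which is what grid quadrature of the u-marginal
    actually requires.  The two disagree for p > 1."""

    min_rule_criterion: bool
    exact_criterion: bool
    min_eigenvalue: float


def hm_normalizability(items: Sequence[HMItem], kernel: HMKernel) -> NormalizabilityReport:
    phi = np.array([it.phi for it in items], dtype=float)
    v2 = kernel.v_eta2
    min_rule = bool(v2 < np.min(1.0 / phi))
    Q = np.diag(phi) - v2 * np.outer(phi, phi)
    lam_min = float(np.linalg.eigvalsh(Q).min())
    return NormalizabilityReport(min_rule_criterion=min_rule,
                                 exact_criterion=lam_min > 0,
                                 min_eigenvalue=lam_min)


def hm_speed_variance_share(item: HMItem, kernel: HMKernel) -> float:
    """Share of Var(ln t_i) = 1/phi_i + v_eta^2 explained by speed."""
    return kernel.v_eta2 / (1.0 / item.phi + kernel.v_eta2)


def hm_speed_variance_share_supremum(phis: Sequence[float]) -> float:
    """Least upper bound of the speed-explained share of log-time variance,
    over speed variances admissible under the restriction
    v_eta^2 < min_i(1/phi_i), maximized over items.

    The share v/(v + 1/phi_i) is increasing in v, so the supremum is attained
    in the limit v -> min_i(1/phi_i) at the highest-precision item; for that
    item 1/phi_i equals the limit, so the bound is 1/2 (unattained).
    """
    phis = np.asarray(phis, dtype=float)
    v_max = float(np.min(1.0 / phis))
    return float(np.max(v_max / (v_max + 1.0 / phis)))


def hm_ci_conditions(items: Sequence[HMItem], kernel: HMKernel):
    """Per item: does the x_i-u_i interaction -rho v phi_i alpha_i / 2 vanish,
    and which factor makes it vanish.  rho = 0 is the only condition that is
    non-trivial (it decouples all accuracies from all times at once)."""
    out = []
    for i, it in enumerate(items):
        factors = []
        if kernel.rho == 0:
            factors.append("rho")
        if it.alpha == 0:
            factors.append("alpha")
        if it.phi == 0:
            factors.append("phi")
        if kernel.v_eta2 == 0:
            factors.append("v_eta2")
        out.append((i, bool(factors), factors))
    return out


def hm_manifest_u_normalization_trace(items: Sequence[HMItem], kernel: HMKernel,
                                      extents=(4.0, 8.0, 16.0, 32.0),
                                      n_grid: int = 161) -> list[float]:
    """log of the manifest normalizer restricted to u in [-L, L]^p, for a
    growing sequence of extents L (accuracies summed exactly over 2^p).

    For a proper manifest distribution the trace stabilizes; when the exact
    positive-definiteness criterion fails the integrand grows like
    exp(+c u^2) and the trace increases without bound under refinement.
    Practical for p <= 2.
    """
    params = hm_manifest_params(items, kernel)
    p = len(items)
    if p > 2:
        raise ValueError("normalization trace is implemented for p <= 2")
    patterns = [np.array(bits, dtype=float)
                for bits in np.ndindex(*([2] * p))]
    trace = []
    for L in extents:
        u = np.linspace(-L, L, n_grid)
        if p == 1:
            pts = u[:, None]
        else:
            g0, g1 = np.meshgrid(u, u, indexing="ij")
            pts = np.column_stack([g0.ravel(), g1.ravel()])
        log_parts = []
        logs = np.empty(pts.shape[0])
        for x in patterns:
            for j in range(pts.shape[0]):
                logs[j] = params.log_density(np.concatenate([x, pts[j]]))
            peak = logs.max()
            vals = np.exp(logs - peak)
            if p == 1:
                integral = np.trapezoid(vals, u)
            else:
                integral = np.trapezoid(
                    np.trapezoid(vals.reshape(n_grid, n_grid), u, axis=1), u)
            log_parts.append(peak + np.log(integral))
        trace.append(float(logsumexp(log_parts)))
    return trace
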
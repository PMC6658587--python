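"""Signed residual time model (SM) for tests with item-level time limits.

Each item i has an easiness beta_i and a deadline d_i; responding at time
t_i in (0, d_i) with accuracy x_i earns the signed residual score
s_i = (2 x_i - 1)(d_i - t_i).  The joint density given ability theta is

    p(x, t | theta) = prod_i (theta + beta_i)
        exp(s_i (theta + beta_i)) / (e^{d_i(theta+beta_i)} - e^{-d_i(theta+beta_i)}),

an exponential family with sufficient statistic s = sum_i s_i.  Integrating
out times gives a 2PL accuracy marginal with discrimination d_i; the
one-to-one pseudo-time transform t* = t (correct) / d - t (incorrect) makes
accuracies and pseudo-times conditionally independent, the latter truncated
exponential on (0, d).  The manifest distribution under a standard-normal
kernel is quadratic in y*r (y = 2x - 1, r = d - t) with a rank-one
interaction matrix, and, conditionally on the residual times, an Ising model
over the signs with random fields r*beta and couplings r r'/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.special import expit, logsumexp

from .expfam import ExpFamItem, KernelSpec, LatentModel, ManifestQuadratic

__all__ = [
    "SMItem",
    "SignedScore",
    "sm_score",
    "sm_joint_logdensity",
    "sm_accuracy_marginal",
    "sm_time_marginal_logdensity",
    "pseudo_transform",
    "pseudo_inverse",
    "sm_pseudo_logpdf",
    "sm_expfam_decomposition",
    "sm_manifest_params",
    "sm_manifest_logdensity",
    "sm_full_conditional",
    "ConditionalComparison",
    "ising_view",
    "ising_conditional_pmf",
    "sm_log_normalizer",
]

_SERIES_RADIUS = 1e-4  # |theta + beta| below which Z_i is evaluated by series


@dataclass(frozen=True)
class SMItem:
    """Easiness beta and deadline d > 0 (seconds); time support (0, d)."""

    beta: float
    d: float

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("deadline d must be positive")


@dataclass(frozen=True)
class SignedScore:
    per_item: np.ndarray  # s_i = (2x_i - 1)(d_i - t_i)
    total: float


def _check_support(t, items: Sequence[SMItem]) -> None:
    for i, (ti, it) in enumerate(zip(np.atleast_1d(t), items)):
        if not 0.0 < ti < it.d:
            raise ValueError(f"t[{i}]={ti} outside the SM support (0, {it.d})")


def sm_score(x, t, items: Sequence[SMItem]) -> SignedScore:
    """Signed residual scores: residual time d - t gained when correct, lost
    when incorrect."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    d = np.array([it.d for it in items], dtype=float)
    for i, ti in enumerate(t):
        if not 0.0 <= ti <= d[i]:
            raise ValueError(f"t[{i}]={ti} outside [0, {d[i]}]")
    s = (2.0 * x - 1.0) * (d - t)
    return SignedScore(per_item=s, total=float(s.sum()))


def sm_log_normalizer(lam: float | np.ndarray, d: float) -> float | np.ndarray:
    """log Z(lam) with Z = (e^{d lam} - e^{-d lam}) / lam, an even function;
    the removable singularity at lam = 0 (Z -> 2d) is handled by a series."""
    lam = np.asarray(lam, dtype=float)
    a = np.abs(lam) * d
    small = np.abs(lam) < _SERIES_RADIUS
    with np.errstate(divide="ignore", invalid="ignore"):
        direct = a + np.log1p(-np.exp(-2.0 * a)) - np.log(np.abs(lam))
    series = np.log(2.0 * d) + np.log1p(a**2 / 6.0 + a**4 / 120.0)
    out = np.where(small, series, direct)
    return float(out) if out.ndim == 0 else out


def _log_w_trunc_exp(lam: float, d: float) -> float:
    """log W with W = (1 - e^{-d lam}) / lam, the truncated-exponential
    normalizer on (0, d); W(0) = d."""
    a = d * lam
    if abs(lam) < _SERIES_RADIUS:
        return float(np.log(d) + np.log1p(-a / 2.0 + a**2 / 6.0 - a**3 / 24.0))
    if lam > 0:
        return float(np.log1p(-np.exp(-a)) - np.log(lam))
    return float(np.log(np.expm1(-a)) - np.log(-lam))


def sm_joint_logdensity(x, t, theta: float, items: Sequence[SMItem]) -> float:
    """log p(x, t | theta) = sum_i [s_i (theta + beta_i) - log Z_i]."""
    _check_support(t, items)
    s = sm_score(x, t, items).per_item
    out = 0.0
    for si, it in zip(s, items):
        lam = theta + it.beta
        out += si * lam - sm_log_normalizer(lam, it.d)
    return float(out)


def sm_accuracy_marginal(x, theta: float, items: Sequence[SMItem]) -> float:
    """P(x | theta): the 2PL with discrimination equal to the deadline d_i
    (product over items)."""
    x = np.atleast_1d(np.asarray(x))
    out = 1.0
    for xi, it in zip(x, items):
        z = it.d * (theta + it.beta)
        out *= float(expit(z if xi == 1 else -z))
    return out


def sm_time_marginal_logdensity(t, theta: float, items: Sequence[SMItem]) -> float:
    """log p(t | theta), accuracies summed out:
    sum_i log[(e^{r lam} + e^{-r lam}) / Z_i], r = d - t."""
    _check_support(t, items)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = 0.0
    for ti, it in zip(t, items):
        lam = theta + it.beta
        r = it.d - ti
        out += np.logaddexp(r * lam, -r * lam) - sm_log_normalizer(lam, it.d)
    return float(out)


def pseudo_transform(x, t, items: Sequence[SMItem]) -> np.ndarray:
    """Pseudo-response times: t* = t when correct, d - t when incorrect."""
    _check_support(t, items)
    x = np.asarray(x)
    t = np.asarray(t, dtype=float)
    d = np.array([it.d for it in items], dtype=float)
    return np.where(x == 1, t, d - t)


def pseudo_inverse(x, t_star, items: Sequence[SMItem]) -> np.ndarray:
    """Invert the pseudo-time transform exactly (it is an involution per item)."""
    _check_support(t_star, items)
    x = np.asarray(x)
    t_star = np.asarray(t_star, dtype=float)
    d = np.array([it.d for it in items], dtype=float)
    return np.where(x == 1, t_star, d - t_star)


def sm_pseudo_logpdf(t_star, theta: float, items: Sequence[SMItem]) -> float:
    """log p(t* | theta): truncated exponentials on (0, d_i) with rate
    theta + beta_i (uniform in the rate -> 0 limit)."""
    _check_support(t_star, items)
    t_star = np.atleast_1d(np.asarray(t_star, dtype=float))
    out = 0.0
    for ti, it in zip(t_star, items):
        lam = theta + it.beta
        out += -ti * lam - _log_w_trunc_exp(lam, it.d)
    return float(out)


def _sm_item_to_expfam(item: SMItem) -> ExpFamItem:
    b, d = item.beta, item.d

    def statistic(x, t, d=d):
        return np.array([(2.0 * x - 1.0) * (d - t)])

    def base_measure_log(x, t, b=b, d=d):
        return (2.0 * x - 1.0) * (d - t) * b

    def log_normalizer(zeta, b=b, d=d):
        return float(sm_log_normalizer(float(zeta[0]) + b, d))

    def log_normalizer_batch(zetas, b=b, d=d):
        return sm_log_normalizer(zetas[:, 0] + b, d)

    return ExpFamItem(statistic=statistic, base_measure_log=base_measure_log,
                      log_normalizer=log_normalizer,
                      log_normalizer_batch=log_normalizer_batch,
                      time_support=(0.0, d), dim=1)


def sm_expfam_decomposition(items: Sequence[SMItem],
                            kernel: KernelSpec | None = None) -> LatentModel:
    """Exponential-family form with statistic s_i = (2x-1)(d-t), base measure
    exp(s_i beta_i) and normalizer (e^{d lam} - e^{-d lam})/lam."""
    kernel = kernel or KernelSpec(mean=np.zeros(1), cov=np.eye(1))
    return LatentModel(items=tuple(_sm_item_to_expfam(it) for it in items),
                       kernel=kernel, latent_dim=1)


def sm_manifest_params(items: Sequence[SMItem],
                       kernel: KernelSpec | None = None,
                       form: str = "residual") -> ManifestQuadratic:
    """Manifest quadratic under a scalar normal kernel (default N(0, 1)).

    form="residual": q = y * r with intercepts beta + m and interactions
    (v^2/2) * ones.  form="pseudo": q = (x, t*) with intercepts
    (d*(beta+m), -(beta+m)) and interactions (v^2/2) (d, -1)(d, -1)'.
    Both are rank one; the quadratic term is (v^2/2)(sum_i q-statistic)^2,
    self-terms included.
    """
    kernel = kernel or KernelSpec(mean=np.zeros(1), cov=np.eye(1))
    if kernel.dim != 1:
        raise ValueError("the SM has a scalar latent trait")
    m = float(kernel.mean[0])
    v2 = float(kernel.cov[0, 0])
    beta = np.array([it.beta for it in items], dtype=float)
    d = np.array([it.d for it in items], dtype=float)
    p = len(items)
    if form == "residual":
        return ManifestQuadratic(intercepts=beta + m,
                                 interactions=0.5 * v2 * np.ones((p, p)),
                                 variable_layout="y*r")
    if form == "pseudo":
        mu = np.concatenate([d * (beta + m), -(beta + m)])
        f = np.concatenate([d, -np.ones(p)])
        return ManifestQuadratic(intercepts=mu,
                                 interactions=0.5 * v2 * np.outer(f, f),
                                 variable_layout="x then t*")
    raise ValueError("form must be 'residual' or 'pseudo'")


def sm_manifest_logdensity(x, t, items: Sequence[SMItem],
                           kernel: KernelSpec | None = None,
                           form: str = "residual") -> float:
    """Unnormalized log manifest density of observed (x, t), routed through
    the requested parameterization (the per-item maps have unit Jacobian,
    so the two forms return the same value)."""
    params = sm_manifest_params(items, kernel, form)
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if form == "residual":
        q = sm_score(x, t, items).per_item
    else:
        q = np.concatenate([x, pseudo_transform(x, t, items)])
    return params.log_density(q)


@dataclass(frozen=True)
class ConditionalComparison:
    """Numeric full conditional vs the printed closed form.

    numeric_value: p(y_i, r_i | rest) from the manifest quadratic, normalized
    by explicit summation/integration over (y_i, r_i).
    printed_value: exp(y r B) / [(e^B - e^{-B}) / B], B = beta_i + sum_{j!=i}
    y_j r_j, evaluated literally.
    numerator_log_ratio: log of (manifest-derived unnormalized numerator /
    printed numerator); equals the self-interaction term v^2 r_i^2 / 2 that
    the printed display omits.
    """

    numeric_value: float
    printed_value: float
    numerator_log_ratio: float


def sm_full_conditional(i: int, y_i: int, r_i: float, rest_y, rest_r,
                        items: Sequence[SMItem],
                        kernel: KernelSpec | None = None) -> ConditionalComparison:
    """Conditional density of (y_i, r_i) given the other items' (y_j, r_j)."""
    kernel = kernel or KernelSpec(mean=np.zeros(1), cov=np.eye(1))
    params = sm_manifest_params(items, kernel, form="residual")
    p = len(items)
    rest_y = np.asarray(rest_y, dtype=float)
    rest_r = np.asarray(rest_r, dtype=float)
    d_i = items[i].d
    if not 0.0 < r_i < d_i:
        raise ValueError(f"r_i={r_i} outside (0, {d_i})")

    def q_at(yi, ri):
        q = np.empty(p)
        q[:i] = rest_y[:i] * rest_r[:i]
        q[i] = yi * ri
        q[i + 1:] = rest_y[i:] * rest_r[i:]
        return q

    log_joint = params.log_density(q_at(y_i, r_i))
    parts = []
    for yy in (-1.0, 1.0):
        val, _ = quad(lambda rr: np.exp(params.log_density(q_at(yy, rr)) - log_joint),
                      0.0, d_i, limit=200)
        parts.append(val)
    numeric = 1.0 / float(sum(parts))  # exp(log_joint - log_marg) with shift

    B = items[i].beta + float(rest_y @ rest_r)
    printed = float(np.exp(y_i * r_i * B - sm_log_normalizer(B, 1.0)))

    # unnormalized numerator relative to the rest-only configuration (q_i = 0)
    q_rest = q_at(y_i, r_i)
    q_rest[i] = 0.0
    log_num = log_joint - params.log_density(q_rest)
    return ConditionalComparison(
        numeric_value=numeric,
        printed_value=printed,
        numerator_log_ratio=float(log_num - y_i * r_i * B),
    )


def ising_view(r, items: Sequence[SMItem]):
    """Random-effects Ising parameters of the conditional pmf of the signs y
    given residual times r: fields mu = r * beta and couplings Sigma = r r'/2."""
    r = np.asarray(r, dtype=float)
    for ri, it in zip(r, items):
        if not abs(ri) < it.d:
            raise ValueError("residual times must satisfy |r_i| < d_i")
    beta = np.array([it.beta for it in items], dtype=float)
    return r * beta, 0.5 * np.outer(r, r)


def ising_conditional_pmf(mu: np.ndarray, sigma: np.ndarray) -> dict[tuple, float]:
    """Normalized Ising pmf over y in {-1, +1}^p by exhaustive enumeration."""
    p = mu.size
    patterns = [np.array([2 * b - 1 for b in bits], dtype=float)
                for bits in np.ndindex(*([2] * p))]
    logs = np.array([y @ mu + y @ sigma @ y for y in patterns])
    probs = np.exp(logs - logsumexp(logs))
    return {tuple(int(v) for v in y): float(pr) for y, pr in zip(patterns, probs)}
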
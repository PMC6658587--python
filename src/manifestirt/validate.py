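"""Runnable validation suite: every oracle equivalence on small toy models.

Each check compares a closed-form quantity against an independent numeric
route (latent quadrature, explicit enumeration, or simulation moments) and
records the discrepancy against its tolerance.  The suite is what the CLI's
``validate`` command runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass

import numpy as np
from scipy.integrate import quad

from . import expfam, hm, sm, dm
from .errors import ImproperLatentDistributionError
from .simulate import SimulationConfig, generate_dataset

__all__ = ["CheckResult", "ValidationReport", "run_validation_suite"]


@dataclass
class CheckResult:
    name: str
    status: str  # "pass" | "fail"
    discrepancy: float
    tolerance: float
    runtime: float


@dataclass
class ValidationReport:
    checks: list

    @property
    def passed(self) -> bool:
        return all(c.status == "pass" for c in self.checks)

    def to_json(self, path=None) -> str:
        payload = {
            "passed": self.passed,
            "checks": [asdict(c) for c in self.checks],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _toy_hm():
    items = [hm.HMItem(alpha=1.2, beta=-0.3, phi=2.0, xi=1.0),
             hm.HMItem(alpha=0.8, beta=0.5, phi=1.5, xi=0.5)]
    kernel = hm.HMKernel(rho=0.4, v_eta2=0.2)
    return items, kernel


def _toy_sm():
    return [sm.SMItem(beta=0.0, d=1.0), sm.SMItem(beta=0.5, d=2.0)]


def _toy_dm():
    return [dm.DMItem(alpha=1.5, beta=0.3, t_er=0.2),
            dm.DMItem(alpha=2.0, beta=-0.4, t_er=0.2)]


def _offset_spread(closed_vals, oracle_vals):
    diff = np.asarray(closed_vals) - np.asarray(oracle_vals)
    return float(diff.max() - diff.min())


def _checks_core():
    rng = np.random.default_rng(20240901)
    out = []

    # zero-item g is exactly the kernel
    model = expfam.LatentModel(items=(), kernel=expfam.KernelSpec(
        mean=np.zeros(1), cov=np.eye(1)), latent_dim=1)
    grid = np.linspace(-5, 5, 101)[:, None]
    disc = float(np.max(np.abs(model.log_g_unnormalized(grid)
                               - model.kernel.logpdf(grid))))
    out.append(("core.zero_items_g_equals_kernel", disc, 1e-12))

    # curved MGF identity vs direct 1-D quadrature
    worst = 0.0
    for _ in range(5):
        r1, r2 = rng.normal(), rng.uniform(0.1, 2.0)
        m, v2 = rng.normal(), rng.uniform(0.3, 2.0)
        closed = expfam.curved_mgf(r1, r2, m, v2)
        val, _ = quad(lambda z: np.exp(r1 * z - 0.5 * r2 * z**2)
                      * np.exp(-0.5 * (z - m) ** 2 / v2) / np.sqrt(2 * np.pi * v2),
                      -np.inf, np.inf)
        worst = max(worst, abs(closed - val))
    out.append(("core.curved_mgf_vs_quadrature", worst, 1e-8))

    # Corollary-style closed form vs latent quadrature (SM toy)
    items = _toy_sm()
    model = sm.sm_expfam_decomposition(items)
    closed, oracle = [], []
    for _ in range(10):
        x = rng.integers(0, 2, size=2)
        t = np.array([rng.uniform(0.05, it.d - 0.05) for it in items])
        closed.append(expfam.manifest_corollary1_log(model, x, t))
        oracle.append(expfam.manifest_theorem1_log(model, x, t))
    out.append(("core.sm_closed_vs_theorem1", _offset_spread(closed, oracle), 1e-6))

    # Dutch identity: closed vs posterior-expectation route
    x, t = np.array([1, 0]), np.array([0.4, 1.2])
    y, w = np.array([0, 1]), np.array([0.7, 0.9])
    r_closed = expfam.dutch_identity_ratio(model, x, t, y, w, mode="closed")
    r_post = expfam.dutch_identity_ratio(model, x, t, y, w,
                                         mode="posterior-quadrature")
    out.append(("core.dutch_identity_ratio", abs(r_closed - r_post)
                / abs(r_closed), 1e-6))

    # posterior moments: closed vs quadrature
    mean_c, cov_c = expfam.posterior_moments_closed(model, x, t)
    mean_q, cov_q = expfam.posterior_moments_quadrature(model, x, t)
    disc = max(float(np.max(np.abs(mean_c - mean_q))),
               float(np.max(np.abs(cov_c - cov_q))))
    out.append(("core.posterior_moments_closed_vs_quadrature", disc, 1e-6))
    return out


def _checks_hm():
    rng = np.random.default_rng(20240902)
    items, kernel = _toy_hm()
    model = hm.hm_expfam_decomposition(items, kernel)
    out = []

    # pointwise reconstruction of 2PL x lognormal
    worst = 0.0
    for _ in range(20):
        x = rng.integers(0, 2, size=2)
        t = rng.uniform(0.3, 4.0, size=2)
        theta, eta = rng.normal(size=2)
        recon = model.log_conditional(x, t, np.array([theta, eta]))
        direct = sum(hm.twopl_log_pmf(int(xi), theta, it)
                     + hm.lognormal_rt_logpdf(ti, eta, it)
                     for xi, ti, it in zip(x, t, items))
        worst = max(worst, abs(recon - direct))
    out.append(("hm.expfam_reconstruction", worst, 1e-10))

    # closed manifest (in u = ln t) vs 2-D latent quadrature (in t); the
    # change of variables contributes the Jacobian sum(u)
    closed, oracle = [], []
    for _ in range(8):
        x = rng.integers(0, 2, size=2)
        t = rng.uniform(0.3, 4.0, size=2)
        closed.append(hm.hm_manifest_logdensity(items, kernel, x, np.log(t)))
        oracle.append(expfam.manifest_theorem1_log(model, x, t) + np.log(t).sum())
    out.append(("hm.manifest_vs_theorem1", _offset_spread(closed, oracle), 1e-6))

    # rank-2 interaction matrix
    params = hm.hm_manifest_params(items, kernel)
    out.append(("hm.interaction_rank_two",
                abs(params.interaction_rank() - 2), 0.5))

    # normalizability boundary: exact criterion flags the divergent case
    bad_kernel = hm.HMKernel(rho=0.0, v_eta2=0.8)
    bad_items = [hm.HMItem(alpha=1.0, beta=0.0, phi=1.0, xi=0.0)] * 2
    rep = hm.hm_normalizability(bad_items, bad_kernel)
    trace = hm.hm_manifest_u_normalization_trace(bad_items, bad_kernel)
    diverges = trace[-1] - trace[-2] > 1.0
    ok = (not rep.exact_criterion) and rep.min_rule_criterion and diverges
    out.append(("hm.normalizability_boundary", 0.0 if ok else 1.0, 0.5))
    return out


def _checks_sm():
    rng = np.random.default_rng(20240903)
    items = _toy_sm()
    out = []

    # joint normalization over {0,1} x (0, d) at several abilities
    worst = 0.0
    for theta in (-2.0, 0.0, 2.0):
        for it in items:
            total = 0.0
            for x in (0, 1):
                val, _ = quad(lambda tt, x=x, it=it: np.exp(
                    sm.sm_joint_logdensity([x], [tt], theta, [it])), 0, it.d,
                    limit=200)
                total += val
            worst = max(worst, abs(total - 1.0))
    out.append(("sm.joint_normalization", worst, 1e-8))

    # factorization p(x, t* | theta) = 2PL x truncated exponential
    worst = 0.0
    for _ in range(20):
        theta = rng.normal()
        x = rng.integers(0, 2, size=2)
        t = np.array([rng.uniform(0.05, it.d - 0.05) for it in items])
        t_star = sm.pseudo_transform(x, t, items)
        lhs = sm.sm_joint_logdensity(x, t, theta, items)
        rhs = (np.log(sm.sm_accuracy_marginal(x, theta, items))
               + sm.sm_pseudo_logpdf(t_star, theta, items))
        worst = max(worst, abs(lhs - rhs))
    out.append(("sm.pseudo_factorization", worst, 1e-10))

    # rank-one interactions in both manifest forms
    r_res = sm.sm_manifest_params(items, form="residual").interaction_rank()
    r_pse = sm.sm_manifest_params(items, form="pseudo").interaction_rank()
    out.append(("sm.interaction_rank_one", abs(r_res - 1) + abs(r_pse - 1), 0.5))

    # bijection invariance of the manifest density value
    worst = 0.0
    for _ in range(10):
        x = rng.integers(0, 2, size=2)
        t = np.array([rng.uniform(0.05, it.d - 0.05) for it in items])
        worst = max(worst, abs(
            sm.sm_manifest_logdensity(x, t, items, form="residual")
            - sm.sm_manifest_logdensity(x, t, items, form="pseudo")))
    out.append(("sm.manifest_bijection_invariance", worst, 1e-10))

    # Ising conditional: manifest conditional pmf of signs equals Ising pmf
    items3 = [sm.SMItem(beta=b, d=d) for b, d in
              zip((-0.5, 0.0, 0.4), (1.0, 1.5, 2.0))]
    r = np.array([0.3, 0.8, 1.1])
    mu, sigma = sm.ising_view(r, items3)
    ising = sm.ising_conditional_pmf(mu, sigma)
    params = sm.sm_manifest_params(items3, form="residual")
    logs = {}
    for ybits in np.ndindex(2, 2, 2):
        y = 2 * np.array(ybits) - 1
        logs[tuple(int(v) for v in y)] = params.log_density(y * r)
    arr = np.array(list(logs.values()))
    probs = np.exp(arr - arr.max())
    probs /= probs.sum()
    worst = max(abs(pr - ising[key]) for key, pr in zip(logs, probs))
    out.append(("sm.ising_conditional", worst, 1e-10))
    return out


def _checks_dm():
    rng = np.random.default_rng(20240904)
    items = _toy_dm()
    out = []

    # joint normalization over {0,1} x (T_er, inf)
    worst = 0.0
    for theta in (-0.5, 0.8):
        it = items[0]
        total = 0.0
        for x in (0, 1):
            val, _ = quad(lambda tt, x=x: np.exp(
                dm.dm_joint_logdensity([x], [tt], theta, [it])),
                it.t_er + 1e-6, it.t_er + 60.0, limit=400)
            total += val
        worst = max(worst, abs(total - 1.0))
    out.append(("dm.joint_normalization", worst, 1e-6))

    # accuracy marginal is the 2PL with discrimination alpha
    worst = 0.0
    for theta in (-1.0, 0.0, 1.2):
        it = items[1]
        val, _ = quad(lambda tt: np.exp(
            dm.dm_joint_logdensity([1], [tt], theta, [it])),
            it.t_er + 1e-6, it.t_er + 60.0, limit=400)
        worst = max(worst, abs(val - dm.dm_accuracy_marginal(1, theta, it)))
    out.append(("dm.accuracy_marginal_2pl", worst, 1e-6))

    # curved-family reconstruction of the joint density
    model = dm.dm_curved_decomposition(items)
    worst = 0.0
    for _ in range(20):
        x = rng.integers(0, 2, size=2)
        t = np.array([it.t_er + rng.uniform(0.1, 3.0) for it in items])
        theta = rng.normal()
        recon = model.log_conditional(x, t, np.array([theta]))
        direct = dm.dm_joint_logdensity(x, t, theta, items)
        worst = max(worst, abs(recon - direct))
    out.append(("dm.curved_reconstruction", worst, 1e-10))

    # explicit quadratic manifest form equals the moment-identity route
    worst = 0.0
    closed, oracle = [], []
    for _ in range(10):
        x = rng.integers(0, 2, size=2)
        t = np.array([it.t_er + rng.uniform(0.1, 3.0) for it in items])
        lhs = dm.dm_manifest_logdensity(x, t, items)
        rhs = expfam.manifest_curved_log(model, x, t)
        worst = max(worst, abs(lhs - rhs))
        closed.append(lhs)
        oracle.append(expfam.manifest_theorem1_log(model, x, t))
    out.append(("dm.manifest_identity_eq12", worst, 1e-12))
    out.append(("dm.manifest_vs_theorem1", _offset_spread(closed, oracle), 1e-6))

    # rank-one interaction factor
    params = dm.dm_manifest_params(items)
    out.append(("dm.interaction_rank_one", abs(params.interaction_rank() - 1), 0.5))
    return out


def _checks_samplers():
    out = []
    # moment checks at moderate n against analytic values (3 SE bands)
    n = 20000
    items, kernel = _toy_hm()
    cfg = SimulationConfig(model="hm", items=items, kernel=kernel,
                           n_persons=n, seed=11, latent_source="kernel")
    table = generate_dataset(cfg)
    merged = table.data.merge(table.latents, on="person_id")
    worst = 0.0
    for iid, it in enumerate(items):
        sub = merged[merged.item_id == iid]
        u = np.log(sub.time.to_numpy())
        resid = u - (it.xi - sub.eta.to_numpy())
        se = np.sqrt(1.0 / it.phi / len(sub))
        worst = max(worst, abs(resid.mean()) / (3 * se))
    out.append(("sampler.hm_logtime_mean", worst, 1.0))

    sm_items = _toy_sm()
    cfg = SimulationConfig(model="sm", items=sm_items,
                           kernel=expfam.KernelSpec(np.zeros(1), np.eye(1)),
                           n_persons=n, seed=12, latent_source="kernel")
    table = generate_dataset(cfg)
    merged = table.data.merge(table.latents, on="person_id")
    # mean signed score matches d/dtheta log Z at the pooled level
    worst = 0.0
    for iid, it in enumerate(sm_items):
        sub = merged[merged.item_id == iid]
        s = (2 * sub.accuracy.to_numpy() - 1) * (it.d - sub.time.to_numpy())
        h = 1e-5
        expected = np.array([
            (sm.sm_log_normalizer(th + it.beta + h, it.d)
             - sm.sm_log_normalizer(th + it.beta - h, it.d)) / (2 * h)
            for th in sub.theta.to_numpy()])
        se = s.std(ddof=1) / np.sqrt(len(s))
        worst = max(worst, abs((s - expected).mean()) / (3 * se))
    out.append(("sampler.sm_mean_score_identity", worst, 1.0))

    dm_items = _toy_dm()
    cfg = SimulationConfig(model="dm", items=dm_items,
                           kernel=expfam.KernelSpec(np.zeros(1), np.eye(1)),
                           n_persons=2000, seed=13, latent_source="kernel")
    table = generate_dataset(cfg)
    merged = table.data.merge(table.latents, on="person_id")
    worst = 0.0
    for iid, it in enumerate(dm_items):
        sub = merged[merged.item_id == iid]
        p_hat = sub.accuracy.mean()
        p_exp = np.mean([dm.dm_accuracy_marginal(1, th, it)
                         for th in sub.theta.to_numpy()])
        se = np.sqrt(p_exp * (1 - p_exp) / len(sub))
        worst = max(worst, abs(p_hat - p_exp) / (3 * se))
    out.append(("sampler.dm_accuracy_rate", worst, 1.0))
    return out


_SCOPES = {
    "core": _checks_core,
    "hm": _checks_hm,
    "sm": _checks_sm,
    "dm": _checks_dm,
    "samplers": _checks_samplers,
}


def run_validation_suite(scope: str = "all") -> ValidationReport:
    """Execute the oracle-equivalence checks; scope is 'all' or one of
    core, hm, sm, dm, samplers."""
    if scope == "all":
        fns = list(_SCOPES.values())
    elif scope in _SCOPES:
        fns = [_SCOPES[scope]]
    else:
        raise ValueError(f"unknown scope '{scope}'")
    checks = []
    for fn in fns:
        start = time.perf_counter()
        try:
            results = fn()
        except ImproperLatentDistributionError as exc:  # pragma: no cover
            checks.append(CheckResult(name=fn.__name__, status="fail",
                                      discrepancy=np.inf, tolerance=0.0,
                                      runtime=time.perf_counter() - start))
            continue
        elapsed = time.perf_counter() - start
        per = elapsed / max(len(results), 1)
        for name, disc, tol in results:
            checks.append(CheckResult(
                name=name, status="pass" if disc <= tol else "fail",
                discrepancy=float(disc), tolerance=float(tol), runtime=per))
    return ValidationReport(checks=checks)
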
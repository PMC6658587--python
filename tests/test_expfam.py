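"""Core exponential-family machinery: the latent distribution g, the
closed-form manifest law and its quadrature oracle, the curved-family moment
identity, posterior moments, and the Dutch identity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from manifestirt import dm, hm, sm
from manifestirt.errors import (
    DivergentExpectationError,
    ImproperLatentDistributionError,
    UnsupportedModelError,
)
from manifestirt.expfam import (
    KernelSpec,
    LatentModel,
    curved_mgf,
    dutch_identity_ratio,
    g_log_normalizer,
    log_g_density,
    manifest_corollary1_log,
    manifest_curved_log,
    manifest_theorem1_log,
    posterior_moments_closed,
    posterior_moments_quadrature,
    posterior_shape_quadrature,
)

from conftest import random_hm_point, random_sm_point


def empty_model(dim=1):
    return LatentModel(items=(), kernel=KernelSpec(mean=np.zeros(dim),
                                                   cov=np.eye(dim)),
                       latent_dim=dim)


class TestLatentDistributionG:
    def test_zero_items_reduces_to_kernel(self):
        model = empty_model()
        assert log_g_density(model, np.zeros(1)) == pytest.approx(
            np.log(0.3989422804014327), abs=1e-12)
        grid = np.linspace(-6, 6, 201)[:, None]
        diff = model.log_g_unnormalized(grid) - model.kernel.logpdf(grid)
        assert np.max(np.abs(diff)) < 1e-12

    def test_zero_items_normalizer_is_one(self):
        assert g_log_normalizer(empty_model()) == 0.0

    def test_single_sm_item_at_origin_uses_z_limit(self, std_kernel_1d):
        # Z_i(0) -> 2d for the signed-residual-time item; the removable
        # singularity must match evaluations just off the origin
        model = sm.sm_expfam_decomposition([sm.SMItem(beta=0.0, d=1.0)],
                                           std_kernel_1d)
        val = log_g_density(model, np.zeros(1))
        assert val == pytest.approx(np.log(2.0 * 0.3989422804014327), abs=1e-9)
        for eps in (1e-6, -1e-6):
            assert log_g_density(model, np.array([eps])) == pytest.approx(
                val, abs=1e-6)

    def test_normalized_density_integrates_to_one(self, sm_items, std_kernel_1d):
        model = sm.sm_expfam_decomposition(sm_items, std_kernel_1d)
        total, _ = quad(lambda z: np.exp(
            log_g_density(model, np.array([z]), normalized=True)), -10, 10,
            limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_hm_normalizer_matches_grid_refinement(self, hm_kernel):
        items = [hm.HMItem(alpha=1.0, beta=0.2, phi=2.0, xi=0.5)]
        model = hm.hm_expfam_decomposition(items, hm_kernel)
        logz = g_log_normalizer(model)
        # independent oracle: wide trapezoid grid, Richardson-style refinement
        vals = []
        for n in (400, 800):
            g0 = np.linspace(-12, 12, n)
            g1 = np.linspace(-12, 12, n)
            pts = np.column_stack([np.repeat(g0, n), np.tile(g1, n)])
            f = np.exp(model.log_g_unnormalized(pts)).reshape(n, n)
            vals.append(np.log(np.trapezoid(np.trapezoid(f, g1, axis=1), g0)))
        assert abs(vals[-1] - vals[-2]) < 1e-8
        assert logz == pytest.approx(vals[-1], abs=1e-6)

    def test_improper_g_raises_structured_error(self):
        # v_eta^2 * sum(phi) = 1.6 >= 1: the eta direction of the integrand
        # grows and Z diverges
        bad = hm.hm_expfam_decomposition(
            [hm.HMItem(alpha=1.0, beta=0.0, phi=1.0, xi=0.0)] * 2,
            hm.HMKernel(rho=0.0, v_eta2=0.8))
        with pytest.raises(ImproperLatentDistributionError):
            g_log_normalizer(bad)


class TestManifestTheorems:
    def test_zero_items_manifest_is_log_one(self):
        assert manifest_theorem1_log(empty_model(), [], []) == pytest.approx(
            0.0, abs=1e-10)

    @pytest.mark.parametrize("model_name", ["sm", "hm"])
    def test_closed_form_matches_quadrature_up_to_constant(
            self, model_name, rng, sm_items, hm_items, hm_kernel, std_kernel_1d):
        if model_name == "sm":
            model = sm.sm_expfam_decomposition(sm_items, std_kernel_1d)
            points = [random_sm_point(rng, sm_items) for _ in range(20)]
        else:
            model = hm.hm_expfam_decomposition(hm_items, hm_kernel)
            points = [random_hm_point(rng, hm_items) for _ in range(20)]
        diffs = [manifest_corollary1_log(model, x, t)
                 - manifest_theorem1_log(model, x, t) for x, t in points]
        assert max(diffs) - min(diffs) < 1e-6

    def test_degenerate_kernel_limit(self, sm_items):
        # V -> 0: differences of evaluations reduce to (S(x,t) - S(y,w))' m
        kernel = KernelSpec(mean=np.array([0.7]), cov=np.array([[1e-10]]))
        model = sm.sm_expfam_decomposition(sm_items, kernel)
        x, t = np.array([1, 0]), np.array([0.4, 1.2])
        y, w = np.array([0, 1]), np.array([0.7, 0.9])
        Sx = model.total_statistic(x, t)
        Sy = model.total_statistic(y, w)
        lhs = (manifest_corollary1_log(model, x, t)
               - model.total_base_measure_log(x, t)
               - manifest_corollary1_log(model, y, w)
               + model.total_base_measure_log(y, w))
        assert lhs == pytest.approx(float((Sx - Sy) @ kernel.mean), abs=1e-8)

    def test_statistic_additive_over_item_blocks(self, sm_items, sm_items3,
                                                 std_kernel_1d, rng):
        combined = sm.sm_expfam_decomposition(sm_items + sm_items3, std_kernel_1d)
        m1 = sm.sm_expfam_decomposition(sm_items, std_kernel_1d)
        m2 = sm.sm_expfam_decomposition(sm_items3, std_kernel_1d)
        x1, t1 = random_sm_point(rng, sm_items)
        x2, t2 = random_sm_point(rng, sm_items3)
        S = combined.total_statistic(np.concatenate([x1, x2]),
                                     np.concatenate([t1, t2]))
        assert S == pytest.approx(m1.total_statistic(x1, t1)
                                  + m2.total_statistic(x2, t2), abs=1e-12)

    def test_support_violation_rejected(self, sm_items, std_kernel_1d):
        model = sm.sm_expfam_decomposition(sm_items, std_kernel_1d)
        with pytest.raises(ValueError, match="support"):
            manifest_theorem1_log(model, [1, 1], [0.5, 2.5])


class TestCurvedMGF:
    @given(r1=st.floats(-3, 3), m=st.floats(-2, 2), v2=st.floats(0.1, 3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_r2_zero_reduces_to_normal_mgf(self, r1, m, v2):
        assert curved_mgf(r1, 0.0, m, v2) == pytest.approx(
            np.exp(r1 * m + 0.5 * r1**2 * v2), rel=1e-12)

    def test_standard_normal_half_square_expectation(self):
        # E exp(-theta^2/2) under N(0,1) is 1/sqrt(2)
        assert curved_mgf(0.0, 1.0, 0.0, 1.0) == pytest.approx(
            0.7071068, abs=1e-7)

    def test_matches_quadrature_at_random_parameters(self, rng):
        for _ in range(10):
            r1 = rng.normal()
            r2 = rng.uniform(0.05, 2.0)
            m = rng.normal()
            v2 = rng.uniform(0.2, 2.5)
            oracle, _ = quad(
                lambda z: np.exp(r1 * z - 0.5 * r2 * z**2)
                * np.exp(-0.5 * (z - m) ** 2 / v2) / np.sqrt(2 * np.pi * v2),
                -np.inf, np.inf)
            assert curved_mgf(r1, r2, m, v2) == pytest.approx(oracle, abs=1e-8)

    def test_divergent_expectation_raises(self):
        with pytest.raises(DivergentExpectationError):
            curved_mgf(0.0, -2.0, 0.0, 1.0)


class TestCurvedManifest:
    def test_matches_1d_quadrature(self, rng):
        items = [dm.DMItem(alpha=1.2, beta=0.4, t_er=0.15)]
        model = dm.dm_curved_decomposition(items)
        diffs = []
        for _ in range(10):
            x = rng.integers(0, 2, size=1)
            t = np.array([0.15 + rng.uniform(0.1, 2.5)])
            diffs.append(manifest_curved_log(model, x, t)
                         - manifest_theorem1_log(model, x, t))
        assert max(diffs) - min(diffs) < 1e-6
        assert np.max(np.abs(diffs)) < 1e-6  # same (unit) normalizing constant

    def test_zero_time_statistic_uses_mgf_branch(self, std_kernel_1d):
        # s_2+ = 0 corresponds to the plain normal MGF branch
        assert curved_mgf(1.3, 0.0, 0.0, 1.0) == pytest.approx(
            np.exp(0.5 * 1.3**2), rel=1e-12)

    def test_reproduces_dm_manifest(self, dm_items, rng):
        model = dm.dm_curved_decomposition(dm_items)
        for _ in range(5):
            x = rng.integers(0, 2, size=2)
            t = np.array([it.t_er + rng.uniform(0.1, 3.0) for it in dm_items])
            assert manifest_curved_log(model, x, t) == pytest.approx(
                dm.dm_manifest_logdensity(x, t, dm_items), abs=1e-12)

    def test_plain_routes_reject_curved_items(self, dm_items):
        model = dm.dm_curved_decomposition(dm_items)
        t = np.array([1.0, 1.0])
        with pytest.raises(UnsupportedModelError):
            manifest_corollary1_log(model, [1, 0], t)
        with pytest.raises(UnsupportedModelError):
            posterior_moments_closed(model, [1, 0], t)
        model_sm = sm.sm_expfam_decomposition(
            [sm.SMItem(beta=0.0, d=1.0)])
        with pytest.raises(UnsupportedModelError):
            manifest_curved_log(model_sm, [1], [0.5])


class TestPosterior:
    def test_zero_items_posterior_is_kernel(self):
        model = empty_model()
        mean, cov = posterior_moments_closed(model, [], [])
        assert mean == pytest.approx(model.kernel.mean)
        assert cov == pytest.approx(model.kernel.cov)

    def test_quadrature_matches_closed_form(self, hm_items, hm_kernel,
                                            sm_items, std_kernel_1d, rng):
        for model, (x, t) in [
            (hm.hm_expfam_decomposition(hm_items, hm_kernel),
             random_hm_point(rng, hm_items)),
            (sm.sm_expfam_decomposition(sm_items, std_kernel_1d),
             random_sm_point(rng, sm_items)),
        ]:
            mean_c, cov_c = posterior_moments_closed(model, x, t)
            mean_q, cov_q = posterior_moments_quadrature(model, x, t)
            assert np.max(np.abs(mean_c - mean_q)) < 1e-6
            assert np.max(np.abs(cov_c - cov_q)) < 1e-6

    def test_posterior_is_normal(self, hm_items, hm_kernel, rng):
        model = hm.hm_expfam_decomposition(hm_items, hm_kernel)
        x, t = random_hm_point(rng, hm_items)
        skew, kurt = posterior_shape_quadrature(model, x, t)
        assert np.max(np.abs(skew)) < 1e-4
        assert np.max(np.abs(kurt)) < 1e-4

    def test_mean_shift_is_linear_in_statistic(self, sm_items, std_kernel_1d):
        model = sm.sm_expfam_decomposition(sm_items, std_kernel_1d)
        x, t = np.array([1, 0]), np.array([0.4, 1.2])
        y, w = np.array([1, 0]), np.array([0.3, 1.2])
        dS = model.total_statistic(x, t) - model.total_statistic(y, w)
        m1, V1 = posterior_moments_closed(model, x, t)
        m2, V2 = posterior_moments_closed(model, y, w)
        assert m1 - m2 == pytest.approx(model.kernel.cov @ dS, abs=1e-12)
        assert V1 == pytest.approx(V2)


class TestDutchIdentity:
    def test_identical_points_give_unit_ratio(self, sm_items, std_kernel_1d):
        model = sm.sm_expfam_decomposition(sm_items, std_kernel_1d)
        x, t = np.array([1, 0]), np.array([0.4, 1.2])
        for mode in ("closed", "posterior-quadrature"):
            assert dutch_identity_ratio(model, x, t, x, t, mode=mode) == \
                pytest.approx(1.0, abs=1e-9)

    def test_ratios_telescope(self, sm_items, std_kernel_1d, rng):
        model = sm.sm_expfam_decomposition(sm_items, std_kernel_1d)
        pts = [random_sm_point(rng, sm_items) for _ in range(3)]
        r_ab = dutch_identity_ratio(model, *pts[0], *pts[1])
        r_bc = dutch_identity_ratio(model, *pts[1], *pts[2])
        r_ac = dutch_identity_ratio(model, *pts[0], *pts[2])
        assert r_ab * r_bc == pytest.approx(r_ac, rel=1e-10)

    def test_posterior_route_agrees_with_closed_form(self, sm_items,
                                                     std_kernel_1d, rng):
        model = sm.sm_expfam_decomposition(sm_items, std_kernel_1d)
        for _ in range(5):
            x, t = random_sm_point(rng, sm_items)
            y, w = random_sm_point(rng, sm_items)
            r_closed = dutch_identity_ratio(model, x, t, y, w, mode="closed")
            r_post = dutch_identity_ratio(model, x, t, y, w,
                                          mode="posterior-quadrature")
            assert r_post == pytest.approx(r_closed, rel=1e-6)


class TestKernelSpecValidation:
    def test_rejects_asymmetric_covariance(self):
        with pytest.raises(ValueError, match="symmetric"):
            KernelSpec(mean=np.zeros(2), cov=np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_rejects_indefinite_covariance(self):
        with pytest.raises(ValueError, match="positive definite"):
            KernelSpec(mean=np.zeros(2), cov=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_latent_model_requires_matching_dimensions(self, sm_items):
        items = tuple(sm.sm_expfam_decomposition(sm_items).items)
        with pytest.raises(ValueError, match="dimension"):
            LatentModel(items=items,
                        kernel=KernelSpec(mean=np.zeros(2), cov=np.eye(2)),
                        latent_dim=2)
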
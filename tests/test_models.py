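import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hierdx import models as M

ST1 = M.structure_for_model(1, 1, 1)
ST2 = M.structure_for_model(2, 6, 3)
ST3 = M.structure_for_model(3, 6, 3)
ST4 = M.structure_for_model(4, 6, 3)
ALL = [ST1, ST2, ST3, ST4]


def random_instance(structure, seed, n=40):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, n)
    x = rng.uniform(-1, 1, n)
    u = rng.integers(0, structure.n_rois, n)
    v = rng.integers(0, structure.n_networks, n)
    theta = rng.normal(0, 0.5, M.parameter_dim(structure))
    return y, x, u, v, theta


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(M.softmax([0.0, 0.0, 0.0]), [1 / 3] * 3)

    def test_closed_form(self):
        np.testing.assert_allclose(
            M.softmax([0.0, np.log(2), np.log(3)]), [1 / 6, 2 / 6, 3 / 6]
        )

    def test_overflow_safe(self):
        p = M.softmax([0.0, 1000.0, 0.0])
        assert np.all(np.isfinite(p))
        assert p[1] == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            M.softmax([0.0, np.inf, 0.0])

    @given(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=6),
        st.floats(-20, 20, allow_nan=False),
    )
    def test_sums_to_one_and_shift_invariant(self, lam, shift):
        p = M.softmax(lam)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(p, M.softmax(np.asarray(lam) + shift), atol=1e-9)


class TestLinearPredictor:
    def test_reference_category_zero(self):
        pv = M.ParameterVector(b0=np.array([5.0, 5.0]), b1=np.array([5.0, 5.0]))
        assert M.linear_predictor(pv, ST1, x=0.7, category="CN") == 0.0

    def test_model1_arithmetic(self):
        pv = M.ParameterVector(b0=np.array([0.0, 0.1]), b1=np.array([0.0, 0.4]))
        assert M.linear_predictor(pv, ST1, x=0.5, category="AD") == pytest.approx(0.3)

    def test_model4_additive_nesting(self):
        g0 = np.zeros((2, 3))
        g1 = np.zeros((2, 3))
        dev0 = np.zeros((2, 6))
        dev1 = np.zeros((2, 6))
        g0[1, 0], dev0[1, 2] = 0.2, -0.05
        g1[1, 0], dev1[1, 2] = 0.3, 0.1
        pv = M.ParameterVector(g0=g0, g1=g1, dev0=dev0, dev1=dev1)
        lam = M.linear_predictor(pv, ST4, x=1.0, category="AD", roi=2, network=0)
        assert lam == pytest.approx(0.2 - 0.05 + 0.3 + 0.1)

    def test_out_of_range_group_raises(self):
        _, _, _, _, theta = random_instance(ST2, 0)
        pv = M.from_unconstrained(theta, ST2)
        with pytest.raises(IndexError):
            M.linear_predictor(pv, ST2, x=0.0, category="AD", roi=99)


class TestPointwiseLoglik:
    def test_known_probability(self):
        # pick b0 so that pi = (0.5, 0.3, 0.2) at x=0, then y=MCI -> ln 0.3
        b0 = np.log(np.array([0.3, 0.2]) / 0.5)
        pv = M.ParameterVector(b0=b0, b1=np.zeros(2))
        ll = M.pointwise_loglik(pv, ST1, y=np.array([1]), x=np.array([0.0]))
        assert ll[0] == pytest.approx(np.log(0.3), abs=1e-12)

    def test_uniform_total(self):
        pv = M.ParameterVector(b0=np.zeros(2), b1=np.zeros(2))
        n = 17
        ll = M.pointwise_loglik(
            pv, ST1, y=np.zeros(n, dtype=int), x=np.zeros(n)
        )
        assert ll.sum() == pytest.approx(-n * np.log(3.0))

    def test_extreme_coefficients_finite(self):
        pv = M.ParameterVector(b0=np.array([500.0, -500.0]), b1=np.zeros(2))
        ll = M.pointwise_loglik(
            pv, ST1, y=np.array([0, 2]), x=np.zeros(2)
        )
        assert np.all(np.isfinite(ll))
        assert np.all(ll <= 0)

    def test_empty_rows_rejected(self):
        pv = M.ParameterVector(b0=np.zeros(2), b1=np.zeros(2))
        with pytest.raises(ValueError):
            M.pointwise_loglik(pv, ST1, y=np.array([]), x=np.array([]))

    @pytest.mark.parametrize("structure", ALL, ids=lambda s: s.level)
    def test_entries_nonpositive(self, structure):
        y, x, u, v, theta = random_instance(structure, 3)
        pv = M.from_unconstrained(theta, structure)
        ll = M.pointwise_loglik(pv, structure, y, x, u, v)
        assert np.all(ll <= 0)


class TestParameterDim:
    def test_model1(self):
        assert M.parameter_dim(ST1) == 4

    def test_model2_tau(self):
        assert M.parameter_dim(M.structure_for_model(2, 76, 8)) == 312

    def test_model3_tau(self):
        assert M.parameter_dim(M.structure_for_model(3, 76, 8)) == 40

    @pytest.mark.parametrize("structure", ALL, ids=lambda s: s.level)
    def test_names_match_dim(self, structure):
        assert len(M.parameter_names(structure)) == M.parameter_dim(structure)


class TestLogPrior:
    def test_model1_mode_at_zero(self):
        priors = M.PriorConfig()
        pv0 = M.ParameterVector(b0=np.zeros(2), b1=np.zeros(2))
        lp0 = M.log_prior(pv0, ST1, priors)
        expected = 2 * (-np.log(0.05) - 0.5 * np.log(2 * np.pi)) + 2 * (
            -np.log(0.2) - 0.5 * np.log(2 * np.pi)
        )
        assert lp0 == pytest.approx(expected)
        pv1 = M.ParameterVector(b0=np.array([0.01, 0.0]), b1=np.zeros(2))
        assert M.log_prior(pv1, ST1, priors) < lp0

    def test_halfnormal_support(self):
        priors = M.PriorConfig()
        rng = np.random.default_rng(0)
        theta = rng.normal(0, 0.1, M.parameter_dim(ST2))
        pv = M.from_unconstrained(theta, ST2)
        pv.sd0 = np.array([1e-12, 1e-12])  # sd -> 0+ stays finite
        assert np.isfinite(M.log_prior(pv, ST2, priors))
        pv.sd0 = np.array([-0.1, 0.1])
        assert M.log_prior(pv, ST2, priors) == -np.inf

    def test_shrinking_sd_concentrates_on_pooling(self):
        # with all group coefficients at the hyper-mean, the group terms
        # contribute G * logN(0|0, sd); removing that known factor leaves a
        # quantity converging to the fixed hyper-parameter density
        priors = M.PriorConfig()
        g = ST2.n_rois
        mu0 = np.array([0.02, -0.01])
        mu1 = np.array([0.1, 0.05])
        limit = (
            M._normal_lpdf(mu0, priors.group_mean_intercept_scale).sum()
            + M._normal_lpdf(mu1, priors.group_mean_slope_scale).sum()
            + M._normal_lpdf(np.zeros(2), priors.group_sd_intercept_scale).sum()
            + M._normal_lpdf(np.zeros(2), priors.group_sd_slope_scale).sum()
        )
        gaps = []
        for sd in (1e-2, 1e-4, 1e-6):
            sds = np.full(2, sd)
            pv = M.ParameterVector(
                mu0=mu0,
                mu1=mu1,
                sd0=sds,
                sd1=sds,
                g0=np.tile(mu0[:, None], (1, g)),
                g1=np.tile(mu1[:, None], (1, g)),
            )
            lp = M.log_prior(pv, ST2, priors)
            # 2 categories x 2 coefficient kinds x g groups of logN(0|0, sd)
            delta_factor = 4 * g * (-np.log(sd) - 0.5 * np.log(2 * np.pi))
            residual = lp - delta_factor
            gaps.append(abs(residual - limit))
        # residual converges monotonically to the hyper-parameter density
        assert gaps[0] >= gaps[1] >= gaps[2]
        assert gaps[2] == pytest.approx(0.0, abs=1e-6)


class TestGradients:
    @pytest.mark.parametrize("structure", ALL, ids=lambda s: s.level)
    @pytest.mark.parametrize("seed", [0, 1])
    def test_analytic_matches_finite_difference(self, structure, seed):
        y, x, u, v, theta = random_instance(structure, seed)
        logp_grad = M.make_logp_grad(structure, M.PriorConfig(), y, x, u, v)
        _, grad = logp_grad(theta)
        h = 1e-6
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            num = (logp_grad(tp)[0] - logp_grad(tm)[0]) / (2 * h)
            assert grad[i] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestNestingConsistency:
    def test_model4_zero_deviations_equals_model3(self):
        y, x, u, v, theta3 = random_instance(ST3, 11)
        g = ST3.n_networks
        # embed model-3 parameters into model 4 with zero ROI deviations
        theta4 = np.zeros(M.parameter_dim(ST4))
        theta4[: 8 + 4 * g] = theta3
        theta4[8 + 4 * g : 8 + 4 * g + 4] = np.log(1e-300)  # tau ~ 0
        pv3 = M.from_unconstrained(theta3, ST3)
        pv4 = M.from_unconstrained(theta4, ST4)
        ll3 = M.pointwise_loglik(pv3, ST3, y, x, u, v)
        ll4 = M.pointwise_loglik(pv4, ST4, y, x, u, v)
        np.testing.assert_allclose(ll3, ll4, atol=1e-12)

    def test_model2_single_roi_equals_model1(self):
        st2_single = M.ModelStructure(level="roi", n_rois=1, n_networks=1)
        rng = np.random.default_rng(12)
        n = 30
        y = rng.integers(0, 3, n)
        x = rng.uniform(-1, 1, n)
        u = np.zeros(n, dtype=int)
        b0 = rng.normal(0, 0.1, 2)
        b1 = rng.normal(0, 0.3, 2)
        pv1 = M.ParameterVector(b0=b0, b1=b1)
        pv2 = M.ParameterVector(
            mu0=b0,
            mu1=b1,
            sd0=np.ones(2),
            sd1=np.ones(2),
            g0=b0[:, None],
            g1=b1[:, None],
        )
        ll1 = M.pointwise_loglik(pv1, ST1, y, x)
        ll2 = M.pointwise_loglik(pv2, st2_single, y, x, u, np.zeros(n, dtype=int))
        np.testing.assert_allclose(ll1, ll2, atol=1e-12)


class TestStructureValidation:
    def test_nested_needs_both_levels(self):
        with pytest.raises(ValueError):
            M.ModelStructure(level="nested", n_rois=1, n_networks=4)

    def test_unknown_level(self):
        with pytest.raises(ValueError):
            M.ModelStructure(level="extra")

    def test_prior_scales_positive(self):
        with pytest.raises(ValueError):
            M.PriorConfig(slope_scale=0.0)
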
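import numpy as np
import pytest

from hierdx.cohort import implied_coefficients
from hierdx.models import PriorConfig, structure_for_model
from hierdx.sampler import PosteriorDraws, SamplerConfig, nuts, sample_posterior

ST1 = structure_for_model(1, 1, 1)


def gauss_target(dim):
    def logp_grad(theta):
        return -0.5 * theta @ theta, -theta

    return logp_grad


class TestNutsCore:
    def test_standard_normal_moments(self):
        cfg = SamplerConfig(n_iterations_per_chain=1500, n_warmup=500, seed=1)
        draws, stats = nuts(gauss_target(4), 4, cfg)
        flat = draws.reshape(-1, 4)
        np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=0.06)
        np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=0.06)
        assert stats["divergent"].sum() == 0

    def test_correlated_gaussian_covariance(self):
        cov = np.array([[2.0, 1.5], [1.5, 2.0]])
        prec = np.linalg.inv(cov)

        def logp_grad(theta):
            return -0.5 * theta @ prec @ theta, -prec @ theta

        cfg = SamplerConfig(n_iterations_per_chain=2000, n_warmup=1000, seed=2)
        draws, _ = nuts(logp_grad, 2, cfg)
        emp = np.cov(draws.reshape(-1, 2).T)
        np.testing.assert_allclose(emp, cov, atol=0.25)

    def test_seed_determinism(self):
        cfg = SamplerConfig(n_iterations_per_chain=400, n_warmup=200, seed=3)
        d1, _ = nuts(gauss_target(3), 3, cfg)
        d2, _ = nuts(gauss_target(3), 3, cfg)
        np.testing.assert_array_equal(d1, d2)

    def test_different_seed_differs(self):
        cfg1 = SamplerConfig(n_iterations_per_chain=400, n_warmup=200, seed=3)
        cfg2 = SamplerConfig(n_iterations_per_chain=400, n_warmup=200, seed=4)
        d1, _ = nuts(gauss_target(3), 3, cfg1)
        d2, _ = nuts(gauss_target(3), 3, cfg2)
        assert not np.allclose(d1, d2)


class TestSamplerConfig:
    def test_retained_count_contract(self):
        assert SamplerConfig().n_retained == 4000

    def test_warmup_must_be_smaller(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations_per_chain=1000, n_warmup=1000)

    def test_needs_two_chains(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_chains=1)


class TestSamplePosterior:
    def test_default_config_draw_count(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.integers(0, 3, n)
        x = rng.uniform(-1, 1, n)
        fit = sample_posterior(
            ST1, PriorConfig(), y, x, config=SamplerConfig(seed=5)
        )
        assert fit.n_draws == 4000
        assert fit.draws.shape == (4, 1000, 4)
        assert fit.log_lik.shape == (4, 1000, n)
        assert not np.isnan(fit.draws).any()

    def test_separated_classes_slope_sign(self):
        # AD rates shifted up: the AD slope must be positive in nearly all draws
        rng = np.random.default_rng(1)
        n = 300
        y = rng.integers(0, 3, n)
        sigma = 0.25
        mu = np.array([0.0, 0.2, 0.5])
        x = rng.normal(mu[y], sigma)
        b0, b1 = implied_coefficients(0.0, 0.5, sigma, 1 / 3, 1 / 3)
        assert b1 > 0
        fit = sample_posterior(
            ST1,
            PriorConfig().scaled(20),
            y,
            x,
            config=SamplerConfig(n_iterations_per_chain=800, n_warmup=400, seed=6),
        )
        ad_slope = fit.stacked()[:, 3]  # b1[AD]
        assert (ad_slope > 0).mean() > 0.99

    def test_flat_data_recovers_prior_sd(self):
        # x == 0 carries no slope information: slope posterior ~ slope prior
        rng = np.random.default_rng(2)
        n = 150
        y = rng.integers(0, 3, n)
        x = np.zeros(n)
        priors = PriorConfig()
        fit = sample_posterior(
            ST1,
            priors,
            y,
            x,
            config=SamplerConfig(seed=7),
        )
        slopes = fit.stacked()[:, 2:4]
        assert slopes.std() == pytest.approx(priors.slope_scale, rel=0.10)

    def test_posterior_contraction_with_n(self):
        sigma = 0.3
        mu = np.array([0.0, 0.15, 0.35])
        truth = {}
        errs = {}
        for n in (200, 2000):
            rng = np.random.default_rng(42)
            y = rng.integers(0, 3, n)
            x = rng.normal(mu[y], sigma)
            fit = sample_posterior(
                ST1,
                PriorConfig().scaled(30),
                y,
                x,
                config=SamplerConfig(
                    n_iterations_per_chain=700, n_warmup=350, seed=8
                ),
            )
            post_mean = fit.stacked().mean(axis=0)
            true = np.array(
                [
                    implied_coefficients(0.0, mu[1], sigma, 1 / 3, 1 / 3)[0],
                    implied_coefficients(0.0, mu[2], sigma, 1 / 3, 1 / 3)[0],
                    implied_coefficients(0.0, mu[1], sigma, 1 / 3, 1 / 3)[1],
                    implied_coefficients(0.0, mu[2], sigma, 1 / 3, 1 / 3)[1],
                ]
            )
            errs[n] = np.linalg.norm(post_mean - true)
        assert errs[2000] < errs[200]

    def test_retained_draws_have_finite_logp(self, model1_toy_fit):
        y, x, fit = model1_toy_fit
        from hierdx.models import make_logp_grad

        logp_grad = make_logp_grad(fit.structure, fit.priors, y, x)
        sub = fit.stacked()[::100]
        assert all(np.isfinite(logp_grad(t)[0]) for t in sub)

    def test_nonfinite_initialization_raises(self):
        def bad(theta):
            return -np.inf, np.zeros_like(theta)

        with pytest.raises(RuntimeError, match="finite"):
            nuts(bad, 2, SamplerConfig(n_iterations_per_chain=20, n_warmup=10))


class TestSerialization:
    def test_round_trip(self, model1_toy_fit, tmp_path):
        _, _, fit = model1_toy_fit
        fit.save(tmp_path / "fitdir")
        back = PosteriorDraws.load(tmp_path / "fitdir")
        np.testing.assert_array_equal(back.draws, fit.draws)
        np.testing.assert_array_equal(back.log_lik, fit.log_lik)
        assert back.param_names == fit.param_names
        assert back.structure == fit.structure
        assert back.config == fit.config
        assert back.divergence_count() == fit.divergence_count()


class TestFunnelDivergences:
    def test_centered_funnel_triggers_divergences(self):
        # Neal's funnel (a centered hierarchy with a tiny effective hyper-sd
        # region) is the canonical geometry that produces divergent
        # transitions; the non-centered model parameterizations avoid it
        dim = 5

        def logp_grad(theta):
            v, z = theta[0], theta[1:]
            s2 = np.exp(v)
            lp = -0.5 * (v / 3.0) ** 2 - 0.5 * np.sum(z * z) / s2 - 0.5 * (dim - 1) * v
            g = np.empty(dim)
            g[0] = -v / 9.0 + 0.5 * np.sum(z * z) / s2 - 0.5 * (dim - 1)
            g[1:] = -z / s2
            return lp, g

        total = 0
        for seed in (0, 1, 2):
            _, stats = nuts(
                logp_grad,
                dim,
                SamplerConfig(n_iterations_per_chain=600, n_warmup=300, seed=seed),
            )
            total += int(stats["divergent"].sum())
        assert total > 0
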
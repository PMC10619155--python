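import numpy as np
import pytest

from hierdx import evaluation as ev
from hierdx.models import PriorConfig, structure_for_model

ST1 = structure_for_model(1, 1, 1)


class TestPriorPredictive:
    def test_default_priors_fair(self):
        res = ev.prior_predictive(ST1, PriorConfig(), n_draws=4000, seed=0)
        np.testing.assert_allclose(res.category_means, 1 / 3, atol=0.02)
        assert res.fair

    def test_probabilities_sum_to_one(self):
        res = ev.prior_predictive(ST1, PriorConfig(), n_draws=1000, seed=1)
        np.testing.assert_allclose(res.probabilities.sum(axis=-1), 1.0, atol=1e-12)

    def test_biased_prior_fails_fairness(self):
        # shift the sampled intercepts far positive for one category
        res = ev.prior_predictive(ST1, PriorConfig(), n_draws=2000, seed=2)
        biased = res.probabilities.copy()
        # direct construction: intercept +5 on AD swamps the softmax
        from hierdx.models import softmax

        rng = np.random.default_rng(3)
        b0 = np.stack(
            [rng.normal(0, 0.05, 2000), rng.normal(5, 0.01, 2000)], axis=1
        )
        lam = np.zeros((2000, 41, 3))
        lam[:, :, 1:] = b0[:, None, :]
        means = softmax(lam).mean(axis=(0, 1))
        assert means[2] > 0.9
        assert not np.all(np.abs(means - 1 / 3) <= 0.02)

    def test_zero_width_priors_exact_third(self):
        res = ev.prior_predictive(
            ST1, PriorConfig().scaled(1e-9), n_draws=1000, seed=4
        )
        np.testing.assert_allclose(res.category_means, 1 / 3, atol=1e-6)
        np.testing.assert_allclose(res.category_sds, 0.0, atol=1e-6)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            ev.prior_predictive(ST1, PriorConfig(), n_draws=100)

    @pytest.mark.parametrize("model", [2, 3, 4])
    def test_hierarchical_defaults_fair(self, model):
        st = structure_for_model(model, 76, 8)
        res = ev.prior_predictive(st, PriorConfig(), n_draws=4000, seed=model)
        assert res.fair, res.category_means


class TestPosteriorPredictive:
    def test_replicate_shape_and_pvalues(self, model1_toy_fit):
        y, x, fit = model1_toy_fit
        res = ev.posterior_predictive_replicate(fit, y, x, n_reps=500, seed=0)
        assert res.replicates.shape == (500, y.size)
        assert res.class_counts.shape == (500, 3)
        np.testing.assert_array_equal(
            res.observed_counts, [np.sum(y == j) for j in range(3)]
        )
        # model fitted to its own data: counts should not be extreme
        assert np.all(res.p_values > 0.05) and np.all(res.p_values < 0.95)

    def test_size_mismatch_rejected(self, model1_toy_fit):
        y, x, fit = model1_toy_fit
        with pytest.raises(ValueError):
            ev.posterior_predictive_replicate(fit, y[:10], x[:10], n_reps=10)

    def test_deterministic_probabilities_all_one_class(self, model1_toy_fit):
        # force pi = (1, 0, 0): every replicated outcome must be CN
        y, x, fit = model1_toy_fit
        import copy

        fake = copy.copy(fit)
        draws = np.zeros_like(fit.draws)
        draws[:, :, 0:2] = -500.0  # intercepts for MCI/AD
        fake.draws = draws
        res = ev.posterior_predictive_replicate(fake, y, x, n_reps=50, seed=1)
        assert np.all(res.replicates == 0)


class TestPsisLoo:
    def test_against_arviz(self, model1_toy_fit):
        import warnings

        import arviz as az

        _, _, fit = model1_toy_fit
        res = ev.psis_loo(fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(
                posterior={"theta": fit.draws},
                log_likelihood={"y": fit.log_lik},
            )
            theirs = az.loo(idata, pointwise=True)
        assert res.elpd_loo == pytest.approx(float(theirs.elpd_loo), abs=0.05)
        np.testing.assert_allclose(
            res.pointwise, theirs.loo_i.values, atol=5e-3
        )

    def test_elpd_nonpositive_and_sums(self, model1_toy_fit):
        _, _, fit = model1_toy_fit
        res = ev.psis_loo(fit)
        assert res.elpd_loo <= 0
        assert np.all(res.pointwise <= 0)
        assert res.elpd_loo == pytest.approx(res.pointwise.sum())
        assert res.se_elpd_loo == pytest.approx(
            np.sqrt(res.n_obs * res.pointwise.var(ddof=1))
        )

    def test_single_observation_identity(self):
        # n=1: elpd equals the log posterior-predictive mass of that point,
        # because LOO leaves nothing else in the training set -> importance
        # weights reduce to the prior-to-posterior ratio. With a synthetic
        # flat log-lik array the weighted average is exact.
        s = 2000
        rng = np.random.default_rng(5)
        ll = np.log(rng.uniform(0.2, 0.4, size=(s, 1)))
        res = ev.psis_loo(ll)
        # brute-force: log( (1/S) sum 1 / mean(1/p) ) form of the n=1 case
        raw = -ll[:, 0]
        raw -= raw.max()
        w = np.exp(raw) / np.exp(raw).sum()
        expected = np.log((w * np.exp(ll[:, 0])).sum())
        assert res.pointwise[0] == pytest.approx(expected, abs=1e-2)

    def test_smoothed_weights_monotone_in_tail(self):
        rng = np.random.default_rng(6)
        lr = rng.standard_t(4, size=4000)
        lw, k = ev._psis_smooth_one(lr.copy())
        order_raw = np.argsort(lr)
        smoothed_sorted = lw[order_raw]
        tail_len = int(min(0.2 * 4000, 3 * np.sqrt(4000)))
        tail = smoothed_sorted[-tail_len:]
        assert np.all(np.diff(tail) >= -1e-12)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match="1000"):
            ev.psis_loo(np.zeros((100, 5)))

    def test_nonfinite_rejected(self):
        ll = np.zeros((2000, 3))
        ll[0, 0] = np.nan
        with pytest.raises(ValueError):
            ev.psis_loo(ll)


class TestCompareModels:
    def _loo_from_pointwise(self, pw, s=2000):
        pw = np.asarray(pw, dtype=float)
        return ev.LooResult(
            pointwise=pw,
            pareto_k=np.zeros(pw.size),
            elpd_loo=float(pw.sum()),
            se_elpd_loo=float(np.sqrt(pw.size * pw.var(ddof=1))),
            mcse_elpd_loo=0.01,
            n_draws=s,
        )

    def test_identical_models_zero_diff(self):
        pw = -np.abs(np.random.default_rng(0).normal(1, 0.3, 50))
        table = ev.compare_models(
            {"a": self._loo_from_pointwise(pw), "b": self._loo_from_pointwise(pw)}
        )
        np.testing.assert_allclose(table["elpd_diff"], 0.0)
        np.testing.assert_allclose(table["se_diff"], 0.0)

    def test_constant_pointwise_difference(self):
        pw = -np.abs(np.random.default_rng(1).normal(1, 0.3, 100))
        table = ev.compare_models(
            {
                "best": self._loo_from_pointwise(pw),
                "worse": self._loo_from_pointwise(pw - 0.5),
            }
        )
        assert list(table["model"]) == ["best", "worse"]
        worse = table[table.model == "worse"].iloc[0]
        assert worse["elpd_diff"] == pytest.approx(-50.0)
        assert worse["se_diff"] == pytest.approx(0.0, abs=1e-9)

    def test_best_row_first_and_nonpositive_diffs(self):
        rng = np.random.default_rng(2)
        results = {
            f"m{i}": self._loo_from_pointwise(-np.abs(rng.normal(1, 0.3, 60)) - i * 0.1)
            for i in range(4)
        }
        table = ev.compare_models(results)
        assert table["elpd_loo"].is_monotonic_decreasing
        assert table.iloc[0]["elpd_diff"] == 0.0
        assert np.all(table["elpd_diff"].iloc[1:] < 0)

    def test_mismatched_observation_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ev.compare_models(
                {
                    "a": self._loo_from_pointwise(-np.ones(10)),
                    "b": self._loo_from_pointwise(-np.ones(11)),
                }
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.compare_models({})
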
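"""Prior predictive simulation, posterior predictive checks, PSIS-LOO and
model comparison.

PSIS-LOO follows the standard Pareto-smoothed importance sampling recipe:
per observation the importance ratios are the reciprocal likelihoods, the
largest ``M = min(0.2 S, 3 sqrt(S))`` ratios are replaced by expected order
statistics of a generalized Pareto distribution fitted to that tail
(Zhang-Stephens posterior-mean estimator), weights are truncated at the raw
maximum, and the per-observation elpd is the weighted likelihood average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .models import ModelStructure, PriorConfig, softmax

__all__ = [
    "PriorPredictiveResult",
    "prior_predictive",
    "PPCResult",
    "posterior_predictive_replicate",
    "LooResult",
    "psis_loo",
    "compare_models",
    "PARETO_K_GOOD",
]

PARETO_K_GOOD = 0.5
PARETO_K_BAD = 0.7
_FAIRNESS_TOL = 0.02


# ---------------------------------------------------------------------------
# prior predictive
# ---------------------------------------------------------------------------


@dataclass
class PriorPredictiveResult:
    """Distribution of predicted class probabilities under the priors alone."""

    category_means: np.ndarray  # (3,)
    category_sds: np.ndarray  # (3,)
    probabilities: np.ndarray  # (n_draws, n_grid, 3)
    fair: bool

    def summary(self) -> pd.DataFrame:
        from .models import CATEGORIES

        return pd.DataFrame(
            {
                "category": CATEGORIES,
                "mean_probability": self.category_means,
                "sd_probability": self.category_sds,
            }
        )


def prior_predictive(
    structure: ModelStructure,
    priors: PriorConfig,
    input_grid: np.ndarray | None = None,
    n_draws: int = 4000,
    seed: int = 0,
) -> PriorPredictiveResult:
    """Push prior draws through the softmax link over an input grid.

    For hierarchical structures each draw instantiates a fresh group (and,
    for the nested structure, a fresh ROI deviation) from the drawn
    hyper-parameters, i.e. the prior predictive for a new cluster. The
    fairness check passes iff every category's mean probability lies within
    1/3 +- 0.02.
    """
    if n_draws < 1000:
        raise ValueError("use at least 1000 prior draws")
    grid = (
        np.linspace(-1.0, 1.0, 41) if input_grid is None else np.asarray(input_grid)
    )
    rng = np.random.default_rng(seed)

    if structure.level == "complete_pooling":
        b0 = rng.normal(0.0, priors.intercept_scale, size=(n_draws, 2))
        b1 = rng.normal(0.0, priors.slope_scale, size=(n_draws, 2))
    else:
        mu0 = rng.normal(0.0, priors.group_mean_intercept_scale, size=(n_draws, 2))
        mu1 = rng.normal(0.0, priors.group_mean_slope_scale, size=(n_draws, 2))
        sd0 = np.abs(rng.normal(0.0, priors.group_sd_intercept_scale, (n_draws, 2)))
        sd1 = np.abs(rng.normal(0.0, priors.group_sd_slope_scale, (n_draws, 2)))
        b0 = rng.normal(mu0, sd0)
        b1 = rng.normal(mu1, sd1)
        if structure.level == "nested":
            t0 = np.abs(
                rng.normal(0.0, priors.nested_roi_intercept_scale, (n_draws, 2))
            )
            t1 = np.abs(rng.normal(0.0, priors.nested_roi_slope_scale, (n_draws, 2)))
            b0 = b0 + rng.normal(0.0, t0)
            b1 = b1 + rng.normal(0.0, t1)

    lam = np.zeros((n_draws, grid.size, 3))
    lam[:, :, 1:] = b0[:, None, :] + b1[:, None, :] * grid[None, :, None]
    probs = softmax(lam)
    means = probs.mean(axis=(0, 1))
    sds = probs.std(axis=(0, 1))
    fair = bool(np.all(np.abs(means - 1.0 / 3.0) <= _FAIRNESS_TOL))
    return PriorPredictiveResult(
        category_means=means, category_sds=sds, probabilities=probs, fair=fair
    )


# ---------------------------------------------------------------------------
# posterior predictive check
# ---------------------------------------------------------------------------


@dataclass
class PPCResult:
    """Replicated outcomes and group-count discrepancy summaries."""

    replicates: np.ndarray  # (n_reps, n_obs) category codes
    class_counts: np.ndarray  # (n_reps, 3)
    observed_counts: np.ndarray  # (3,)
    p_values: np.ndarray  # (3,) fraction of replicates >= observed count
    mean_probabilities: np.ndarray  # (n_obs, 3) posterior mean class probs


def posterior_predictive_replicate(
    fit,
    y: np.ndarray,
    x: np.ndarray,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> PPCResult:
    """Draw replicated outcome vectors from the fitted model.

    Each replicate uses one retained posterior draw; the summary reports the
    per-category replicated class counts and the fraction of replicates at
    or above the observed count (a posterior-predictive p-value).
    """
    from .models import _lambda_matrix, from_unconstrained  # local: private use

    y = np.asarray(y, dtype=np.int64)
    x = np.asarray(x, dtype=float)
    n = y.size
    u = np.zeros(n, dtype=np.int64) if u is None else np.asarray(u, dtype=np.int64)
    v = np.zeros(n, dtype=np.int64) if v is None else np.asarray(v, dtype=np.int64)
    if fit.log_lik is not None and fit.log_lik.shape[-1] != n:
        raise ValueError(
            f"fit stores {fit.log_lik.shape[-1]} observations but {n} were given"
        )

    thetas = fit.stacked()
    rng = np.random.default_rng(seed)
    idx = (
        rng.choice(thetas.shape[0], size=n_reps, replace=False)
        if n_reps <= thetas.shape[0]
        else rng.integers(0, thetas.shape[0], size=n_reps)
    )

    reps = np.empty((n_reps, n), dtype=np.int64)
    prob_sum = np.zeros((n, 3))
    for k, t in enumerate(idx):
        pv = from_unconstrained(thetas[t], fit.structure)
        p = softmax(_lambda_matrix(pv, fit.structure, x, u, v))
        prob_sum += p
        cum = p.cumsum(axis=1)
        draw = rng.uniform(size=n)
        reps[k] = (draw[:, None] > cum).sum(axis=1)

    counts = np.stack([(reps == j).sum(axis=1) for j in range(3)], axis=1)
    observed = np.array([(y == j).sum() for j in range(3)])
    p_values = (counts >= observed[None, :]).mean(axis=0)
    return PPCResult(
        replicates=reps,
        class_counts=counts,
        observed_counts=observed,
        p_values=p_values,
        mean_probabilities=prob_sum / n_reps,
    )


# ---------------------------------------------------------------------------
# PSIS-LOO
# ---------------------------------------------------------------------------


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto to exceedances ``x`` (Zhang & Stephens 2009).

    Returns (k, sigma) with the weak regularizing prior on k used by the
    reference implementations.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.floor(np.sqrt(n)))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x).mean(axis=1)
    log_lik = n * (np.log(-(b / k)) - k - 1.0)
    weights = 1.0 / np.exp(log_lik - log_lik[:, None]).sum(axis=1)
    b_post = (b * weights).sum()
    k_post = np.log1p(-b_post * x).mean()
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return float(k_post), float(sigma)


def _psis_smooth_one(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Smooth one observation's log importance ratios; returns normalized
    log weights and the Pareto shape k."""
    s = log_ratios.size
    lw = log_ratios - log_ratios.max()
    tail_len = int(min(0.2 * s, 3.0 * np.sqrt(s)))
    k_hat = np.inf
    if tail_len >= 5:
        order = np.argsort(lw)
        tail_ids = order[-tail_len:]
        cutoff = lw[order[-tail_len - 1]]
        tail = np.exp(lw[tail_ids]) - np.exp(cutoff)
        if np.ptp(tail) > 0:
            k_hat, sigma = _gpd_fit(tail)
            if np.isfinite(k_hat):
                # expected order statistics of the fitted Pareto tail
                q = (np.arange(1, tail_len + 1) - 0.5) / tail_len
                if abs(k_hat) < 1e-12:
                    quantiles = -sigma * np.log1p(-q)
                else:
                    quantiles = sigma / k_hat * ((1 - q) ** (-k_hat) - 1.0)
                smoothed = np.log(np.exp(cutoff) + quantiles)
                # order-preserving: assign by rank within the tail
                rank = np.argsort(np.argsort(lw[tail_ids]))
                lw[tail_ids] = smoothed[rank]
    lw = np.minimum(lw, 0.0)  # truncate at the raw maximum
    lw = lw - logsumexp(lw)
    return lw, float(k_hat if tail_len >= 5 else np.inf)


@dataclass
class LooResult:
    """PSIS-LOO estimate of the expected log pointwise predictive density."""

    pointwise: np.ndarray  # (n_obs,) elpd contributions
    pareto_k: np.ndarray  # (n_obs,)
    elpd_loo: float
    se_elpd_loo: float
    mcse_elpd_loo: float
    n_draws: int

    @property
    def n_obs(self) -> int:
        return self.pointwise.size

    def k_summary(self) -> dict[str, int]:
        k = self.pareto_k
        return {
            "good": int((k <= PARETO_K_GOOD).sum()),
            "ok": int(((k > PARETO_K_GOOD) & (k <= PARETO_K_BAD)).sum()),
            "bad": int((k > PARETO_K_BAD).sum()),
        }


def psis_loo(fit_or_log_lik) -> LooResult:
    """PSIS-LOO from a fit's stored pointwise log-likelihood array.

    Accepts a :class:`~hierdx.sampler.PosteriorDraws` or a raw (n_draws,
    n_obs) log-likelihood matrix.
    """
    if hasattr(fit_or_log_lik, "stacked_log_lik"):
        log_lik = fit_or_log_lik.stacked_log_lik()
    else:
        log_lik = np.atleast_2d(np.asarray(fit_or_log_lik, dtype=float))
    if not np.all(np.isfinite(log_lik)):
        raise ValueError("log-likelihood array contains non-finite values")
    s, n = log_lik.shape
    if s < 1000:
        raise ValueError(f"PSIS-LOO needs at least 1000 draws, got {s}")

    pointwise = np.empty(n)
    ks = np.empty(n)
    mcse_sq = 0.0
    for i in range(n):
        lw, k = _psis_smooth_one(-log_lik[:, i])
        ks[i] = k
        elpd_i = logsumexp(lw + log_lik[:, i])
        pointwise[i] = elpd_i
        # delta-method MC error of log of the self-normalized estimate
        w = np.exp(lw)
        e_hat = np.exp(elpd_i)
        mcse_sq += float((w**2 * (np.exp(log_lik[:, i]) - e_hat) ** 2).sum()) / (
            e_hat**2
        )

    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * pointwise.var(ddof=1))) if n > 1 else 0.0
    return LooResult(
        pointwise=pointwise,
        pareto_k=ks,
        elpd_loo=elpd,
        se_elpd_loo=se,
        mcse_elpd_loo=float(np.sqrt(mcse_sq)),
        n_draws=s,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

COMPARABLE_SE_DIFF = 4.0


def compare_models(loo_results: dict[str, LooResult]) -> pd.DataFrame:
    """Rank models by elpd_loo, best first, with differences to the best.

    All results must be computed on the same observations (same pointwise
    length and order). ``se_diff`` is the standard error of the pointwise
    elpd differences against the best model.
    """
    if not loo_results:
        raise ValueError("no LOO results to compare")
    n_obs = {name: r.n_obs for name, r in loo_results.items()}
    if len(set(n_obs.values())) != 1:
        raise ValueError(f"observation sets differ across models: {n_obs}")
    n = next(iter(n_obs.values()))

    ordered = sorted(loo_results.items(), key=lambda kv: kv[1].elpd_loo, reverse=True)
    best_name, best = ordered[0]
    rows = []
    for name, res in ordered:
        diff = res.pointwise - best.pointwise
        elpd_diff = float(diff.sum())
        se_diff = float(np.sqrt(n * diff.var(ddof=1))) if name != best_name else 0.0
        rows.append(
            {
                "model": name,
                "elpd_diff": 0.0 if name == best_name else elpd_diff,
                "se_diff": se_diff,
                "elpd_loo": res.elpd_loo,
                "se_elpd_loo": res.se_elpd_loo,
                "comparable_to_best": bool(se_diff < COMPARABLE_SE_DIFF),
            }
        )
    return pd.DataFrame(rows)
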
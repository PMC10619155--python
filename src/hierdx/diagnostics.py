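"""Convergence and accuracy diagnostics for chain-structured draws.

Implements rank-normalized split R-hat, bulk/tail effective sample size via
Geyer's initial monotone positive sequence, and the Monte-Carlo standard
error of the posterior mean. All functions take draws shaped
(chain, iteration); results are cross-checked against ArviZ in the test
suite but computed independently here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "split_rhat",
    "ess_bulk",
    "ess_tail",
    "mcse_mean",
    "divergence_count",
    "DiagnosticsReport",
    "diagnose",
]

RHAT_THRESHOLD = 1.05


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """Halve each chain, doubling the chain count."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be (chain, iteration)")
    n_chains, n_iter = draws.shape
    if n_chains < 2:
        raise ValueError("split R-hat needs at least 2 chains")
    if n_iter < 4:
        raise ValueError("need at least 4 draws per chain")
    half = n_iter // 2
    return np.vstack([draws[:, :half], draws[:, half : 2 * half]])


def _rank_normalize(draws: np.ndarray) -> np.ndarray:
    """Map draws to normal scores via their pooled fractional ranks."""
    flat = draws.ravel()
    ranks = sps.rankdata(flat, method="average")
    return sps.norm.ppf((ranks - 3.0 / 8.0) / (flat.size + 0.25)).reshape(draws.shape)


def _rhat_basic(chains: np.ndarray) -> float:
    m, n = chains.shape
    chain_means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return np.nan
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def split_rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat (max of the bulk and folded statistic).

    Returns ``nan`` for degenerate (zero-variance) draws — undefined rather
    than spuriously 1.0.
    """
    chains = _split_chains(draws)
    if np.allclose(chains, chains.ravel()[0]):
        return np.nan
    bulk = _rhat_basic(_rank_normalize(chains))
    folded = _rhat_basic(_rank_normalize(np.abs(chains - np.median(chains))))
    return float(np.nanmax([bulk, folded]))


def _ess_from_chains(chains: np.ndarray) -> float:
    """Effective sample size via FFT autocovariance and Geyer pairing."""
    m, n = chains.shape
    if np.allclose(chains, chains.ravel()[0]):
        return np.nan
    # per-chain autocovariance via FFT
    centered = chains - chains.mean(axis=1, keepdims=True)
    pad = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, pad, axis=1)
    acov = np.fft.irfft(f * np.conj(f), pad, axis=1)[:, :n].real / n

    chain_var = acov[:, 0] * n / (n - 1)
    mean_var = chain_var.mean()
    var_plus = mean_var * (n - 1) / n
    if m > 1:
        var_plus += chains.mean(axis=1).var(ddof=1)
    if var_plus == 0:
        return np.nan

    mean_acov = acov.mean(axis=0)
    # Geyer initial positive + monotone sequence on paired correlations
    rho_even = 1.0
    rho_odd = 1.0 - (mean_var - mean_acov[1]) / var_plus
    pair = rho_even + rho_odd
    total = 0.0
    t = 2
    while pair >= 0:
        total += pair
        if t + 1 >= n:
            break
        rho_even = 1.0 - (mean_var - mean_acov[t]) / var_plus
        rho_odd = 1.0 - (mean_var - mean_acov[t + 1]) / var_plus
        new_pair = rho_even + rho_odd
        pair = min(pair, max(new_pair, 0.0)) if new_pair >= 0 else -1.0
        t += 2
    tau = max(-1.0 + 2.0 * total, 1.0 / np.log10(m * n + 10))
    ess = m * n / tau
    return float(min(ess, m * n * np.log10(m * n)))


def ess_bulk(draws: np.ndarray) -> float:
    """Bulk effective sample size of rank-normalized split chains."""
    chains = _split_chains(draws)
    if np.allclose(chains, chains.ravel()[0]):
        return np.nan
    return _ess_from_chains(_rank_normalize(chains))


def ess_tail(draws: np.ndarray) -> float:
    """Tail ESS: minimum ESS of the 5% and 95% quantile indicators."""
    chains = _split_chains(draws)
    if np.allclose(chains, chains.ravel()[0]):
        return np.nan
    out = []
    for q in (0.05, 0.95):
        ind = (chains <= np.quantile(chains, q)).astype(float)
        out.append(_ess_from_chains(_rank_normalize(ind)))
    return float(np.nanmin(out))


def ess_mean(draws: np.ndarray) -> float:
    """ESS of the raw draws (no rank normalization) for mean estimation."""
    chains = _split_chains(draws)
    if np.allclose(chains, chains.ravel()[0]):
        return np.nan
    return _ess_from_chains(chains)


def mcse_mean(draws: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean: sd / sqrt(ESS)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        # single chain of iid-style draws: fall back to a 2-chain split
        half = draws.size // 2
        draws = np.vstack([draws[:half], draws[half : 2 * half]])
    if np.allclose(draws, draws.ravel()[0]):
        return 0.0
    ess = ess_mean(draws)
    if not np.isfinite(ess) or ess <= 0:
        return np.nan
    return float(draws.std(ddof=1) / np.sqrt(ess))


def divergence_count(stats: dict) -> int:
    """Total post-warmup divergent transitions from sampler statistics."""
    if "divergent" not in stats:
        raise ValueError("sampler statistics lack a 'divergent' field")
    return int(np.asarray(stats["divergent"]).sum())


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence table plus global flags."""

    table: pd.DataFrame  # columns: parameter, rhat, ess_bulk, ess_tail, mcse_mean
    n_divergent: int
    max_rhat: float
    min_ess_bulk: float
    converged: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = (
            f"divergences={self.n_divergent}  max_rhat={self.max_rhat:.4f}  "
            f"min_ess_bulk={self.min_ess_bulk:.0f}  converged={self.converged}"
        )
        return head + "\n" + self.table.to_string(index=False)


def diagnose(fit) -> DiagnosticsReport:
    """Compute the full diagnostics report for a :class:`PosteriorDraws`."""
    draws = fit.draws  # (chain, iter, param)
    rows = []
    for p, name in enumerate(fit.param_names):
        d = draws[:, :, p]
        rows.append(
            {
                "parameter": name,
                "rhat": split_rhat(d),
                "ess_bulk": ess_bulk(d),
                "ess_tail": ess_tail(d),
                "mcse_mean": mcse_mean(d),
            }
        )
    table = pd.DataFrame(rows)
    n_div = divergence_count(fit.stats)
    max_rhat = float(np.nanmax(table["rhat"]))
    min_ess = float(np.nanmin(table["ess_bulk"]))
    return DiagnosticsReport(
        table=table,
        n_divergent=n_div,
        max_rhat=max_rhat,
        min_ess_bulk=min_ess,
        converged=(n_div == 0) and (max_rhat <= RHAT_THRESHOLD),
    )
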
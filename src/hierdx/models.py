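"""The four multinomial logistic model structures.

All models share the same categorical likelihood: a three-category outcome
(CN is the reference with linear propensity fixed at 0) and a single
predictor, the normalized rate of change. They differ only in how the
intercept and slope of the MCI and AD propensities are pooled:

* ``complete_pooling`` — one global intercept/slope pair per category.
* ``roi``             — per-ROI coefficients drawn from a shared Gaussian.
* ``network``         — per-network coefficients drawn from a shared Gaussian.
* ``nested``          — network-level coefficients plus zero-mean per-ROI
  deviations, i.e. ROIs nested within networks.

Hierarchical coefficients use the non-centered parameterization
(coefficient = mean + sd * raw) and positive scales are sampled on the log
scale with the Jacobian correction, so the posterior handed to the sampler
is an unconstrained smooth density with an analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Callable, Literal

import numpy as np

__all__ = [
    "PoolingLevel",
    "ModelStructure",
    "PriorConfig",
    "ParameterVector",
    "softmax",
    "parameter_dim",
    "parameter_names",
    "split_unconstrained",
    "from_unconstrained",
    "linear_predictor",
    "pointwise_loglik",
    "log_prior",
    "make_logp_grad",
    "loglik_for_draws",
    "linear_predictors_for_draws",
    "structure_for_model",
    "CATEGORIES",
]

PoolingLevel = Literal["complete_pooling", "roi", "network", "nested"]

#: Outcome categories in model order; index 0 is the reference.
CATEGORIES: tuple[str, ...] = ("CN", "MCI", "AD")

_LEVELS: dict[int, PoolingLevel] = {
    1: "complete_pooling",
    2: "roi",
    3: "network",
    4: "nested",
}


@dataclass(frozen=True)
class ModelStructure:
    """Which pooling level is active and the grouping dimensions."""

    level: PoolingLevel
    n_rois: int = 1
    n_networks: int = 1
    n_categories: int = 3
    n_predictors: int = 1
    reference_category: str = "CN"

    def __post_init__(self) -> None:
        if self.level not in _LEVELS.values():
            raise ValueError(f"unknown pooling level {self.level!r}")
        if self.level == "roi" and self.n_rois < 1:
            raise ValueError("roi-level pooling requires n_rois >= 1")
        if self.level == "network" and self.n_networks < 1:
            raise ValueError("network-level pooling requires n_networks >= 1")
        if self.level == "nested" and (self.n_rois <= 1 or self.n_networks <= 1):
            raise ValueError("nested pooling requires n_rois > 1 and n_networks > 1")

    @property
    def model_number(self) -> int:
        return {v: k for k, v in _LEVELS.items()}[self.level]

    @property
    def n_groups(self) -> int:
        """Group count of the primary (non-nested) grouping factor."""
        if self.level == "roi":
            return self.n_rois
        if self.level in ("network", "nested"):
            return self.n_networks
        return 1


def structure_for_model(model: int, n_rois: int, n_networks: int) -> ModelStructure:
    """Convenience constructor from a model number 1-4."""
    if model not in _LEVELS:
        raise ValueError(f"model must be 1..4, got {model}")
    return ModelStructure(level=_LEVELS[model], n_rois=n_rois, n_networks=n_networks)


@dataclass(frozen=True)
class PriorConfig:
    """Prior scales (all Gaussian / Half-Normal standard deviations).

    The complete-pooling scales are the reference defaults (0.05 intercept,
    0.2 slope); the hierarchical hyperprior scales default to the same
    values, with the nested ROI-deviation scales at half the network-level
    scales. All must be positive.
    """

    intercept_scale: float = 0.05
    slope_scale: float = 0.2
    group_mean_intercept_scale: float = 0.05
    group_mean_slope_scale: float = 0.2
    group_sd_intercept_scale: float = 0.05
    group_sd_slope_scale: float = 0.2
    nested_roi_intercept_scale: float = 0.025
    nested_roi_slope_scale: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def scaled(self, factor: float) -> "PriorConfig":
        """A copy with every scale multiplied by ``factor``."""
        return replace(
            self, **{f.name: getattr(self, f.name) * factor for f in fields(self)}
        )


@dataclass
class ParameterVector:
    """Constrained-space view of one parameter draw.

    Arrays are indexed ``[category, ...]`` with category order (MCI, AD);
    reference-category coefficients are identically zero and not stored.
    Only the fields relevant to the structure's pooling level are set.
    """

    # model 1
    b0: np.ndarray | None = None  # (2,)
    b1: np.ndarray | None = None
    # models 2/3: group coefficients and their hyper-parameters
    mu0: np.ndarray | None = None  # (2,)
    mu1: np.ndarray | None = None
    sd0: np.ndarray | None = None  # (2,)
    sd1: np.ndarray | None = None
    g0: np.ndarray | None = None  # (2, G)
    g1: np.ndarray | None = None
    # model 4: per-ROI deviations around the network coefficients
    dev0: np.ndarray | None = None  # (2, U)
    dev1: np.ndarray | None = None
    tau0: np.ndarray | None = None  # (2,)
    tau1: np.ndarray | None = None


def softmax(lambdas: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    lam = np.asarray(lambdas, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("softmax inputs must be finite")
    m = lam.max(axis=-1, keepdims=True)
    e = np.exp(lam - m)
    return e / e.sum(axis=-1, keepdims=True)


def parameter_dim(structure: ModelStructure) -> int:
    """Number of free parameters (reference category excluded)."""
    if structure.level == "complete_pooling":
        return 4
    if structure.level in ("roi", "network"):
        g = structure.n_groups
        return 8 + 4 * g
    # nested: network block + deviation scales + per-ROI raw deviations
    return 8 + 4 * structure.n_networks + 4 + 4 * structure.n_rois


def parameter_names(structure: ModelStructure) -> list[str]:
    """Flat names matching the unconstrained parameter layout."""
    cats = CATEGORIES[1:]
    if structure.level == "complete_pooling":
        return [f"b0[{c}]" for c in cats] + [f"b1[{c}]" for c in cats]

    def hyper(tag: str) -> list[str]:
        return [f"{tag}[{c}]" for c in cats]

    g = structure.n_groups
    gname = "roi" if structure.level == "roi" else "net"
    names = hyper("mu0") + hyper("mu1") + hyper("log_sd0") + hyper("log_sd1")
    for z in ("z0", "z1"):
        names += [f"{z}[{c},{gname}{i}]" for c in cats for i in range(g)]
    if structure.level == "nested":
        u = structure.n_rois
        names += hyper("log_tau0") + hyper("log_tau1")
        for z in ("zd0", "zd1"):
            names += [f"{z}[{c},roi{i}]" for c in cats for i in range(u)]
    return names


def split_unconstrained(
    theta: np.ndarray, structure: ModelStructure
) -> dict[str, np.ndarray]:
    """Split a flat unconstrained vector into named blocks.

    Works on a single vector ``(dim,)`` or a batch ``(S, dim)``; block arrays
    keep the leading batch axes.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != parameter_dim(structure):
        raise ValueError(
            f"theta has {theta.shape[-1]} entries, expected {parameter_dim(structure)}"
        )
    lead = theta.shape[:-1]
    pos = 0

    def take(*shape: int) -> np.ndarray:
        nonlocal pos
        size = int(np.prod(shape))
        block = theta[..., pos : pos + size].reshape(lead + shape)
        pos += size
        return block

    if structure.level == "complete_pooling":
        return {"b0": take(2), "b1": take(2)}
    g = structure.n_groups
    out = {
        "mu0": take(2),
        "mu1": take(2),
        "log_sd0": take(2),
        "log_sd1": take(2),
        "z0": take(2, g),
        "z1": take(2, g),
    }
    if structure.level == "nested":
        out["log_tau0"] = take(2)
        out["log_tau1"] = take(2)
        out["zd0"] = take(2, structure.n_rois)
        out["zd1"] = take(2, structure.n_rois)
    return out


def from_unconstrained(theta: np.ndarray, structure: ModelStructure) -> ParameterVector:
    """Map an unconstrained vector to the constrained named parameters."""
    b = split_unconstrained(theta, structure)
    if structure.level == "complete_pooling":
        return ParameterVector(b0=b["b0"], b1=b["b1"])
    sd0 = np.exp(b["log_sd0"])
    sd1 = np.exp(b["log_sd1"])
    pv = ParameterVector(
        mu0=b["mu0"],
        mu1=b["mu1"],
        sd0=sd0,
        sd1=sd1,
        g0=b["mu0"][..., None] + sd0[..., None] * b["z0"],
        g1=b["mu1"][..., None] + sd1[..., None] * b["z1"],
    )
    if structure.level == "nested":
        pv.tau0 = np.exp(b["log_tau0"])
        pv.tau1 = np.exp(b["log_tau1"])
        pv.dev0 = pv.tau0[..., None] * b["zd0"]
        pv.dev1 = pv.tau1[..., None] * b["zd1"]
    return pv


def _category_index(category: int | str) -> int:
    if isinstance(category, str):
        try:
            return CATEGORIES.index(category)
        except ValueError:
            raise ValueError(f"unknown category {category!r}") from None
    if category not in (0, 1, 2):
        raise ValueError(f"category index must be 0..2, got {category}")
    return int(category)


def linear_predictor(
    params: ParameterVector,
    structure: ModelStructure,
    x: float,
    category: int | str,
    roi: int | None = None,
    network: int | None = None,
) -> float:
    """Linear propensity of one category for one observation.

    ``roi`` and ``network`` are 0-based group codes. The reference category
    always yields 0.
    """
    j = _category_index(category)
    if j == 0:
        return 0.0
    c = j - 1
    if structure.level == "complete_pooling":
        return float(params.b0[c] + params.b1[c] * x)
    if structure.level == "roi":
        if roi is None or not 0 <= roi < structure.n_rois:
            raise IndexError(f"roi code {roi} out of range for {structure.n_rois} ROIs")
        return float(params.g0[c, roi] + params.g1[c, roi] * x)
    if structure.level == "network":
        if network is None or not 0 <= network < structure.n_networks:
            raise IndexError(
                f"network code {network} out of range for "
                f"{structure.n_networks} networks"
            )
        return float(params.g0[c, network] + params.g1[c, network] * x)
    if roi is None or not 0 <= roi < structure.n_rois:
        raise IndexError(f"roi code {roi} out of range for {structure.n_rois} ROIs")
    if network is None or not 0 <= network < structure.n_networks:
        raise IndexError(
            f"network code {network} out of range for {structure.n_networks} networks"
        )
    intercept = params.g0[c, network] + params.dev0[c, roi]
    slope = params.g1[c, network] + params.dev1[c, roi]
    return float(intercept + slope * x)


def _lambda_matrix(
    params: ParameterVector,
    structure: ModelStructure,
    x: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
) -> np.ndarray:
    """Propensity matrix (N, 3); column 0 is the reference (all zeros)."""
    n = x.shape[0]
    lam = np.zeros((n, 3))
    for c in range(2):
        if structure.level == "complete_pooling":
            lam[:, c + 1] = params.b0[c] + params.b1[c] * x
        elif structure.level == "roi":
            lam[:, c + 1] = params.g0[c, u] + params.g1[c, u] * x
        elif structure.level == "network":
            lam[:, c + 1] = params.g0[c, v] + params.g1[c, v] * x
        else:
            lam[:, c + 1] = (
                params.g0[c, v]
                + params.dev0[c, u]
                + (params.g1[c, v] + params.dev1[c, u]) * x
            )
    return lam


def pointwise_loglik(
    params: ParameterVector,
    structure: ModelStructure,
    y: np.ndarray,
    x: np.ndarray,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
) -> np.ndarray:
    """Per-observation log-probability of the observed category."""
    y = np.asarray(y, dtype=np.int64)
    x = np.asarray(x, dtype=float)
    if y.size == 0:
        raise ValueError("rows must be nonempty")
    u = np.zeros_like(y) if u is None else np.asarray(u, dtype=np.int64)
    v = np.zeros_like(y) if v is None else np.asarray(v, dtype=np.int64)
    lam = _lambda_matrix(params, structure, x, u, v)
    m = lam.max(axis=1)
    lse = m + np.log(np.exp(lam - m[:, None]).sum(axis=1))
    return lam[np.arange(y.size), y] - lse


_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def _normal_lpdf(value: np.ndarray, scale: float | np.ndarray) -> np.ndarray:
    return -0.5 * (value / scale) ** 2 - np.log(scale) - _HALF_LOG_2PI


def log_prior(
    params: ParameterVector, structure: ModelStructure, priors: PriorConfig
) -> float:
    """Joint log prior density in constrained space (up to the Half-Normal
    support constant, consistent across calls). Non-positive scales give
    ``-inf`` so the density acts as a rejection during sampling."""
    if structure.level == "complete_pooling":
        return float(
            _normal_lpdf(params.b0, priors.intercept_scale).sum()
            + _normal_lpdf(params.b1, priors.slope_scale).sum()
        )

    for sd in (params.sd0, params.sd1):
        if np.any(sd <= 0):
            return -np.inf
    total = (
        _normal_lpdf(params.mu0, priors.group_mean_intercept_scale).sum()
        + _normal_lpdf(params.mu1, priors.group_mean_slope_scale).sum()
        + _normal_lpdf(params.sd0, priors.group_sd_intercept_scale).sum()
        + _normal_lpdf(params.sd1, priors.group_sd_slope_scale).sum()
        + _normal_lpdf(params.g0 - params.mu0[:, None], params.sd0[:, None]).sum()
        + _normal_lpdf(params.g1 - params.mu1[:, None], params.sd1[:, None]).sum()
    )
    if structure.level == "nested":
        for tau in (params.tau0, params.tau1):
            if np.any(tau <= 0):
                return -np.inf
        total += (
            _normal_lpdf(params.tau0, priors.nested_roi_intercept_scale).sum()
            + _normal_lpdf(params.tau1, priors.nested_roi_slope_scale).sum()
            + _normal_lpdf(params.dev0, params.tau0[:, None]).sum()
            + _normal_lpdf(params.dev1, params.tau1[:, None]).sum()
        )
    return float(total)


def make_logp_grad(
    structure: ModelStructure,
    priors: PriorConfig,
    y: np.ndarray,
    x: np.ndarray,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
    """Build the unconstrained log-posterior and its analytic gradient.

    The returned callable is the hot path of the sampler: one call per
    leapfrog step. Constant terms of the density are dropped.
    """
    y = np.asarray(y, dtype=np.int64)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("rows must be nonempty")
    u = np.zeros(n, dtype=np.int64) if u is None else np.asarray(u, dtype=np.int64)
    v = np.zeros(n, dtype=np.int64) if v is None else np.asarray(v, dtype=np.int64)
    if structure.level in ("roi", "nested") and u.max(initial=-1) >= structure.n_rois:
        raise IndexError("roi code out of range")
    if (
        structure.level in ("network", "nested")
        and v.max(initial=-1) >= structure.n_networks
    ):
        raise IndexError("network code out of range")

    # one-hot outcome for the two non-reference categories
    Y = np.zeros((n, 2))
    Y[y == 1, 0] = 1.0
    Y[y == 2, 1] = 1.0
    idx = np.arange(n)

    def lik_and_resid(lam: np.ndarray) -> tuple[float, np.ndarray]:
        m = lam.max(axis=1)
        ex = np.exp(lam - m[:, None])
        denom = ex.sum(axis=1)
        loglik = float((lam[idx, y] - m - np.log(denom)).sum())
        p = ex / denom[:, None]
        return loglik, Y - p[:, 1:]

    if structure.level == "complete_pooling":
        inv_i2 = 1.0 / priors.intercept_scale**2
        inv_s2 = 1.0 / priors.slope_scale**2

        def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
            b0 = theta[0:2]
            b1 = theta[2:4]
            lam = np.zeros((n, 3))
            lam[:, 1:] = b0 + b1 * x[:, None]
            loglik, e = lik_and_resid(lam)
            logp = loglik - 0.5 * inv_i2 * (b0 @ b0) - 0.5 * inv_s2 * (b1 @ b1)
            grad = np.empty(4)
            grad[0:2] = e.sum(axis=0) - inv_i2 * b0
            grad[2:4] = e.T @ x - inv_s2 * b1
            return logp, grad

        return logp_grad

    g = structure.n_groups
    gid = u if structure.level == "roi" else v
    inv_m0 = 1.0 / priors.group_mean_intercept_scale**2
    inv_m1 = 1.0 / priors.group_mean_slope_scale**2
    inv_s0 = 1.0 / priors.group_sd_intercept_scale**2
    inv_s1 = 1.0 / priors.group_sd_slope_scale**2

    if structure.level in ("roi", "network"):

        def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
            mu0, mu1 = theta[0:2], theta[2:4]
            l0, l1 = theta[4:6], theta[6:8]
            z0 = theta[8 : 8 + 2 * g].reshape(2, g)
            z1 = theta[8 + 2 * g : 8 + 4 * g].reshape(2, g)
            sd0, sd1 = np.exp(l0), np.exp(l1)
            c0 = mu0[:, None] + sd0[:, None] * z0
            c1 = mu1[:, None] + sd1[:, None] * z1

            lam = np.zeros((n, 3))
            lam[:, 1] = c0[0, gid] + c1[0, gid] * x
            lam[:, 2] = c0[1, gid] + c1[1, gid] * x
            loglik, e = lik_and_resid(lam)

            ex_w = e * x[:, None]
            S0 = np.stack(
                [np.bincount(gid, weights=e[:, c], minlength=g) for c in range(2)]
            )
            S1 = np.stack(
                [np.bincount(gid, weights=ex_w[:, c], minlength=g) for c in range(2)]
            )

            logp = (
                loglik
                - 0.5 * (z0 * z0).sum()
                - 0.5 * (z1 * z1).sum()
                - 0.5 * inv_m0 * (mu0 @ mu0)
                - 0.5 * inv_m1 * (mu1 @ mu1)
                - 0.5 * inv_s0 * (sd0 @ sd0)
                - 0.5 * inv_s1 * (sd1 @ sd1)
                + l0.sum()
                + l1.sum()
            )
            grad = np.empty(theta.size)
            grad[0:2] = S0.sum(axis=1) - inv_m0 * mu0
            grad[2:4] = S1.sum(axis=1) - inv_m1 * mu1
            grad[4:6] = sd0 * (z0 * S0).sum(axis=1) - inv_s0 * sd0**2 + 1.0
            grad[6:8] = sd1 * (z1 * S1).sum(axis=1) - inv_s1 * sd1**2 + 1.0
            grad[8 : 8 + 2 * g] = (sd0[:, None] * S0 - z0).ravel()
            grad[8 + 2 * g : 8 + 4 * g] = (sd1[:, None] * S1 - z1).ravel()
            return logp, grad

        return logp_grad

    # nested: network coefficients + per-ROI deviations
    n_u = structure.n_rois
    inv_t0 = 1.0 / priors.nested_roi_intercept_scale**2
    inv_t1 = 1.0 / priors.nested_roi_slope_scale**2
    base = 8 + 4 * g

    def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        mu0, mu1 = theta[0:2], theta[2:4]
        l0, l1 = theta[4:6], theta[6:8]
        z0 = theta[8 : 8 + 2 * g].reshape(2, g)
        z1 = theta[8 + 2 * g : base].reshape(2, g)
        lt0, lt1 = theta[base : base + 2], theta[base + 2 : base + 4]
        zd0 = theta[base + 4 : base + 4 + 2 * n_u].reshape(2, n_u)
        zd1 = theta[base + 4 + 2 * n_u : base + 4 + 4 * n_u].reshape(2, n_u)

        sd0, sd1 = np.exp(l0), np.exp(l1)
        t0, t1 = np.exp(lt0), np.exp(lt1)
        c0 = mu0[:, None] + sd0[:, None] * z0
        c1 = mu1[:, None] + sd1[:, None] * z1
        d0 = t0[:, None] * zd0
        d1 = t1[:, None] * zd1

        lam = np.zeros((n, 3))
        lam[:, 1] = c0[0, v] + d0[0, u] + (c1[0, v] + d1[0, u]) * x
        lam[:, 2] = c0[1, v] + d0[1, u] + (c1[1, v] + d1[1, u]) * x
        loglik, e = lik_and_resid(lam)

        ex_w = e * x[:, None]
        SN0 = np.stack(
            [np.bincount(v, weights=e[:, c], minlength=g) for c in range(2)]
        )
        SN1 = np.stack(
            [np.bincount(v, weights=ex_w[:, c], minlength=g) for c in range(2)]
        )
        SR0 = np.stack(
            [np.bincount(u, weights=e[:, c], minlength=n_u) for c in range(2)]
        )
        SR1 = np.stack(
            [np.bincount(u, weights=ex_w[:, c], minlength=n_u) for c in range(2)]
        )

        logp = (
            loglik
            - 0.5 * (z0 * z0).sum()
            - 0.5 * (z1 * z1).sum()
            - 0.5 * (zd0 * zd0).sum()
            - 0.5 * (zd1 * zd1).sum()
            - 0.5 * inv_m0 * (mu0 @ mu0)
            - 0.5 * inv_m1 * (mu1 @ mu1)
            - 0.5 * inv_s0 * (sd0 @ sd0)
            - 0.5 * inv_s1 * (sd1 @ sd1)
            - 0.5 * inv_t0 * (t0 @ t0)
            - 0.5 * inv_t1 * (t1 @ t1)
            + l0.sum()
            + l1.sum()
            + lt0.sum()
            + lt1.sum()
        )
        grad = np.empty(theta.size)
        grad[0:2] = SN0.sum(axis=1) - inv_m0 * mu0
        grad[2:4] = SN1.sum(axis=1) - inv_m1 * mu1
        grad[4:6] = sd0 * (z0 * SN0).sum(axis=1) - inv_s0 * sd0**2 + 1.0
        grad[6:8] = sd1 * (z1 * SN1).sum(axis=1) - inv_s1 * sd1**2 + 1.0
        grad[8 : 8 + 2 * g] = (sd0[:, None] * SN0 - z0).ravel()
        grad[8 + 2 * g : base] = (sd1[:, None] * SN1 - z1).ravel()
        grad[base : base + 2] = t0 * (zd0 * SR0).sum(axis=1) - inv_t0 * t0**2 + 1.0
        grad[base + 2 : base + 4] = (
            t1 * (zd1 * SR1).sum(axis=1) - inv_t1 * t1**2 + 1.0
        )
        grad[base + 4 : base + 4 + 2 * n_u] = (t0[:, None] * SR0 - zd0).ravel()
        grad[base + 4 + 2 * n_u : base + 4 + 4 * n_u] = (
            t1[:, None] * SR1 - zd1
        ).ravel()
        return logp, grad

    return logp_grad


def loglik_for_draws(
    thetas: np.ndarray,
    structure: ModelStructure,
    y: np.ndarray,
    x: np.ndarray,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Pointwise log-likelihood matrix (n_draws, n_obs) for a draw batch."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    y = np.asarray(y, dtype=np.int64)
    out = np.empty((thetas.shape[0], y.size))
    for start in range(0, thetas.shape[0], chunk):
        block = thetas[start : start + chunk]
        for i, theta in enumerate(block):
            pv = from_unconstrained(theta, structure)
            out[start + i] = pointwise_loglik(pv, structure, y, x, u, v)
    return out


def linear_predictors_for_draws(
    thetas: np.ndarray,
    structure: ModelStructure,
    x_grid: np.ndarray,
    roi: int | None = None,
    network: int | None = None,
) -> np.ndarray:
    """Propensity array (n_draws, n_grid, 3) over an input grid.

    For the nested structure, passing only ``network`` gives the
    network-level curve (ROI deviations set to zero); passing ``roi``
    requires its ``network`` as well.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    x_grid = np.asarray(x_grid, dtype=float)
    s, m = thetas.shape[0], x_grid.size
    lam = np.zeros((s, m, 3))
    pv = from_unconstrained(thetas, structure)  # batched blocks (S, ...)

    for c in range(2):
        if structure.level == "complete_pooling":
            b0 = pv.b0[:, c : c + 1]
            b1 = pv.b1[:, c : c + 1]
        elif structure.level == "roi":
            if roi is None or not 0 <= roi < structure.n_rois:
                raise IndexError(f"roi code {roi} out of range")
            b0 = pv.g0[:, c, roi : roi + 1]
            b1 = pv.g1[:, c, roi : roi + 1]
        elif structure.level == "network":
            if roi is not None:
                raise ValueError(
                    "the network-level structure has no ROI-specific "
                    "coefficients; request a network-level curve instead"
                )
            if network is None or not 0 <= network < structure.n_networks:
                raise IndexError(f"network code {network} out of range")
            b0 = pv.g0[:, c, network : network + 1]
            b1 = pv.g1[:, c, network : network + 1]
        else:
            if network is None or not 0 <= network < structure.n_networks:
                raise IndexError(f"network code {network} out of range")
            b0 = pv.g0[:, c, network : network + 1]
            b1 = pv.g1[:, c, network : network + 1]
            if roi is not None:
                if not 0 <= roi < structure.n_rois:
                    raise IndexError(f"roi code {roi} out of range")
                b0 = b0 + pv.dev0[:, c, roi : roi + 1]
                b1 = b1 + pv.dev1[:, c, roi : roi + 1]
        lam[:, :, c + 1] = b0 + b1 * x_grid[None, :]
    return lam
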
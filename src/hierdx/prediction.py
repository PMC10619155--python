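"""Posterior class-probability curves over a grid of input rates.

Curves summarize, per category, the posterior mean probability and
equal-tailed 60%/89% credible bands over a grid spanning the observed range
of relative annualized rates (raw units; normalization is applied
internally using the scale stored with the fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import CORTICAL_THICKNESS, TAU_SUVR, AtlasMap
from .models import CATEGORIES, linear_predictors_for_draws, softmax

__all__ = ["PredictionCurve", "posterior_curves", "curve_report", "GRID_RANGES"]

#: Observed min/max relative annualized rates per modality (raw units).
GRID_RANGES = {
    TAU_SUVR: (-0.42, 0.71),
    CORTICAL_THICKNESS: (-0.26, 0.23),
}

#: Equal-tailed credible levels reported around the mean curve.
BAND_LEVELS = (0.60, 0.89)


@dataclass
class PredictionCurve:
    modality: str
    target_kind: str  # "roi" | "network" | "global"
    target_id: str
    network: str | None
    braak_stage: int | None
    x_raw: np.ndarray
    x_norm: np.ndarray
    mean: np.ndarray  # (n_grid, 3)
    lo60: np.ndarray
    hi60: np.ndarray
    lo89: np.ndarray
    hi89: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame (one row per grid point and category)."""
        rows = []
        for j, cat in enumerate(CATEGORIES):
            rows.append(
                pd.DataFrame(
                    {
                        "target": self.target_id,
                        "category": cat,
                        "x_raw": self.x_raw,
                        "x_norm": self.x_norm,
                        "mean": self.mean[:, j],
                        "lo60": self.lo60[:, j],
                        "hi60": self.hi60[:, j],
                        "lo89": self.lo89[:, j],
                        "hi89": self.hi89[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _resolve_grid(fit, grid, n_points):
    modality = fit.meta.get("modality", TAU_SUVR)
    scale = float(fit.meta.get("scale", 1.0))
    if grid is None:
        lo, hi = GRID_RANGES[modality]
        x_raw = np.linspace(lo, hi, n_points)
    else:
        x_raw = np.asarray(grid, dtype=float)
    return modality, x_raw, x_raw / scale


def posterior_curves(
    fit,
    roi: int | None = None,
    network: str | None = None,
    grid: np.ndarray | None = None,
    n_points: int = 101,
) -> PredictionCurve:
    """Posterior prediction curve for one ROI or network.

    ``roi`` is an atlas roi_index; ``network`` a network name. The nested
    structure supports both targets (a network curve sets the ROI deviations
    to zero); the network-only structure supports networks only, the
    ROI-only structure ROIs only, and complete pooling needs no target.
    """
    structure = fit.structure
    modality, x_raw, x_norm = _resolve_grid(fit, grid, n_points)

    roi_levels: list[int] = fit.meta.get("roi_levels", [])
    network_levels: list[str] = fit.meta.get("network_levels", [])

    roi_code = net_code = None
    net_name = None
    if roi is not None:
        if structure.level in ("network", "complete_pooling"):
            raise ValueError(
                f"the {structure.level!r} structure has no ROI-specific "
                "coefficients; request a network-level curve instead"
            )
        if roi not in roi_levels:
            raise KeyError(f"roi_index {roi} not present in the fitted data")
        roi_code = roi_levels.index(roi)
        roi_nets: list[str] = fit.meta.get("roi_networks", [])
        if structure.level == "nested":
            net_name = roi_nets[roi_code]
            net_code = network_levels.index(net_name)
    elif network is not None:
        if structure.level in ("roi", "complete_pooling"):
            raise ValueError(
                f"the {structure.level!r} structure has no network-specific "
                "coefficients"
            )
        if network not in network_levels:
            raise KeyError(f"network {network!r} not present in the fitted data")
        net_code = network_levels.index(network)
        net_name = network
    elif structure.level != "complete_pooling":
        raise ValueError("specify a roi or a network target for this structure")

    lam = linear_predictors_for_draws(
        fit.stacked(), structure, x_norm, roi=roi_code, network=net_code
    )
    probs = softmax(lam)  # (S, m, 3)
    mean = probs.mean(axis=0)
    bands = {}
    for level in BAND_LEVELS:
        alpha = (1.0 - level) / 2.0
        bands[level] = (
            np.quantile(probs, alpha, axis=0),
            np.quantile(probs, 1.0 - alpha, axis=0),
        )

    if roi is not None:
        kind, tid = "roi", str(roi)
    elif network is not None:
        kind, tid = "network", network
    else:
        kind, tid = "global", "all"
    return PredictionCurve(
        modality=modality,
        target_kind=kind,
        target_id=tid,
        network=net_name,
        braak_stage=None,
        x_raw=x_raw,
        x_norm=x_norm,
        mean=mean,
        lo60=bands[0.60][0],
        hi60=bands[0.60][1],
        lo89=bands[0.89][0],
        hi89=bands[0.89][1],
    )


def curve_report(curves: list[PredictionCurve], atlas: AtlasMap) -> dict:
    """Group ROI curves by network, ordered by Braak stage.

    Returns ``{"groups": {network: [curves...]}, "reference_lines": ...}``;
    the reference lines mark the 1/3 probability level and a zero input
    rate, for plotting.
    """
    if not curves:
        raise ValueError("no curves to report")
    modalities = {c.modality for c in curves}
    if len(modalities) != 1:
        raise ValueError(f"curves mix modalities: {sorted(modalities)}")
    modality = next(iter(modalities))

    def sort_key(c: PredictionCurve):
        return (c.braak_stage is None, c.braak_stage or 0, c.target_id)

    groups: dict[str, list[PredictionCurve]] = {
        net: [] for net in atlas.networks(modality)  # type: ignore[arg-type]
    }
    for c in curves:
        if c.target_kind == "roi":
            rec = atlas.by_index(int(c.target_id))
            c.network = rec.network
            c.braak_stage = rec.braak_stage
            groups[rec.network].append(c)
        elif c.target_kind == "network":
            groups[c.target_id].append(c)
    for net in groups:
        groups[net].sort(key=sort_key)
    return {
        "modality": modality,
        "groups": groups,
        "reference_lines": {"probability": 1.0 / 3.0, "input": 0.0},
    }


def render_curves(curves: list[PredictionCurve], path: str) -> None:
    """Render curves to a figure file (one panel per curve)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(curves)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), squeeze=False)
    colors = {"CN": "tab:blue", "MCI": "tab:red", "AD": "tab:green"}
    for ax, curve in zip(axes[0], curves):
        for j, cat in enumerate(CATEGORIES):
            ax.plot(curve.x_raw, curve.mean[:, j], color=colors[cat], label=cat)
            ax.fill_between(
                curve.x_raw,
                curve.lo89[:, j],
                curve.hi89[:, j],
                color=colors[cat],
                alpha=0.15,
            )
            ax.fill_between(
                curve.x_raw,
                curve.lo60[:, j],
                curve.hi60[:, j],
                color=colors[cat],
                alpha=0.25,
            )
        ax.axhline(1.0 / 3.0, ls="--", c="grey", lw=0.8)
        ax.axvline(0.0, ls="--", c="grey", lw=0.8)
        title = curve.target_id
        if curve.braak_stage is not None:
            title += f" (Braak {curve.braak_stage})"
        ax.set_title(title)
        ax.set_xlabel("relative annualized rate")
        ax.set_ylim(0, 1)
    axes[0, 0].set_ylabel("posterior probability")
    axes[0, 0].legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
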
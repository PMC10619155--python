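"""Synthetic longitudinal cohort generator with an analytic coefficient oracle.

The fitted models are discriminative (diagnosis | rate); the simulator runs
the other way, drawing each (subject, ROI) rate from an equal-variance
Gaussian whose mean depends on diagnosis, network and ROI:

    rate ~ Normal(mu_d + a[d, network] + b[d, roi], within_cell_sd)

Equal-variance Gaussian class-conditionals induce an exactly linear
multinomial-logit posterior, so the true intercepts and slopes that a
well-specified model should recover exist in closed form
(:func:`implied_coefficients`). Baseline/follow-up pairs are back-computed
so the relative annualized rate reproduces the sampled rate exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import CORTICAL_NETWORKS, CORTICAL_THICKNESS, TAU_SUVR, AtlasMap, Modality, build_atlas
from .rates import DIAGNOSES, LongitudinalMeasure

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "simulate_cohort",
    "implied_coefficients",
    "reduced_atlas",
    "measures_to_frame",
]

#: Median inter-scan interval in days for each modality.
_DEFAULT_INTERVALS = {TAU_SUVR: 418.0, CORTICAL_THICKNESS: 378.0}


def implied_coefficients(
    mu_ref: float, mu_j: float, sigma: float, p_ref: float, p_j: float
) -> tuple[float, float]:
    """True multinomial-logit coefficients for Gaussian class-conditionals.

    For classes with equal variance ``sigma**2``, means ``mu_ref`` (the
    reference) and ``mu_j``, and prior probabilities ``p_ref``/``p_j``, the
    posterior log-odds of class j against the reference are linear in x with

        slope     = (mu_j - mu_ref) / sigma^2
        intercept = (mu_ref^2 - mu_j^2) / (2 sigma^2) + ln(p_j / p_ref)
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (0 < p_ref < 1 and 0 < p_j < 1):
        raise ValueError("class probabilities must be in (0, 1)")
    slope = (mu_j - mu_ref) / sigma**2
    intercept = (mu_ref**2 - mu_j**2) / (2 * sigma**2) + np.log(p_j / p_ref)
    return float(intercept), float(slope)


def reduced_atlas(n_rois_per_hemi: int = 6, n_networks: int = 4) -> AtlasMap:
    """A small bilateral atlas for reduced-scale experiments.

    Builds ``n_rois_per_hemi`` cortical regions per hemisphere assigned
    cyclically to the first ``n_networks`` cortical networks.
    """
    if not 1 <= n_networks <= len(CORTICAL_NETWORKS):
        raise ValueError(f"n_networks must be 1..{len(CORTICAL_NETWORKS)}")
    if n_rois_per_hemi < n_networks:
        raise ValueError("need at least one ROI per network")
    rows = []
    for i in range(n_rois_per_hemi):
        rows.append(
            {
                "roi_index": i + 1,
                "roi_label": f"SynthRegion{i + 1:02d}",
                "roi_abbrev": f"SR{i + 1:02d}",
                "network": CORTICAL_NETWORKS[i % n_networks],
                "braak_stage": (i % 6) + 1,
                "cortical": 1,
            }
        )
    return build_atlas(pd.DataFrame(rows))


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate the study's cohort structure
    (113 subjects split 72/23/18, bilateral atlas, ~1-year scan intervals)."""

    n_per_group: tuple[int, int, int] = (72, 23, 18)  # CN, MCI, AD
    modality: Modality = TAU_SUVR
    atlas: AtlasMap | None = None
    interval_location_days: float | None = None  # default per modality
    interval_spread_days: float = 50.0
    class_base_means: tuple[float, float, float] = (0.0, 0.06, 0.14)
    within_cell_sd: float = 0.12
    roi_effect_sd: float = 0.02
    network_effect_sd: float = 0.04
    baseline_location: float = 1.5
    baseline_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("group sizes must be >= 1")
        for name in (
            "within_cell_sd",
            "baseline_location",
            "baseline_sd",
            "interval_spread_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.roi_effect_sd < 0 or self.network_effect_sd < 0:
            raise ValueError("effect sds must be non-negative")

    @property
    def interval_median(self) -> float:
        if self.interval_location_days is not None:
            return self.interval_location_days
        return _DEFAULT_INTERVALS[self.modality]


@dataclass
class GroundTruth:
    """Realized generative effects and the implied logit coefficients."""

    modality: Modality
    roi_indices: list[int]
    networks: list[str]
    class_probs: np.ndarray  # (3,)
    base_means: np.ndarray  # (3,)
    network_shifts: np.ndarray  # (3, V)
    roi_shifts: np.ndarray  # (3, U)
    cell_means: np.ndarray  # (3, U) per-ROI class-conditional means
    within_cell_sd: float
    extras: dict = field(default_factory=dict)

    def implied_roi_coefficients(self, scale: float = 1.0):
        """True per-ROI intercepts and slopes (MCI, AD rows) on the scale of
        ``x = rate / scale``; CN coefficients are identically zero."""
        n_roi = len(self.roi_indices)
        intercepts = np.zeros((2, n_roi))
        slopes = np.zeros((2, n_roi))
        for c, j in enumerate((1, 2)):  # MCI, AD against CN
            for r in range(n_roi):
                b0, b1 = implied_coefficients(
                    self.cell_means[0, r],
                    self.cell_means[j, r],
                    self.within_cell_sd,
                    self.class_probs[0],
                    self.class_probs[j],
                )
                intercepts[c, r] = b0
                slopes[c, r] = b1 * scale
        return intercepts, slopes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "modality": self.modality,
            "roi_indices": self.roi_indices,
            "networks": self.networks,
            "class_probs": self.class_probs.tolist(),
            "base_means": self.base_means.tolist(),
            "network_shifts": self.network_shifts.tolist(),
            "roi_shifts": self.roi_shifts.tolist(),
            "cell_means": self.cell_means.tolist(),
            "within_cell_sd": self.within_cell_sd,
            "extras": self.extras,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[LongitudinalMeasure], GroundTruth]:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    Returns the scan-pair measures (one per subject and ROI) and the
    realized ground truth against which posterior recovery can be judged.
    """
    rng = np.random.default_rng(config.seed)
    atlas = config.atlas if config.atlas is not None else build_atlas()
    records = atlas.records(config.modality)
    roi_indices = [r.roi_index for r in sorted(records, key=lambda r: r.roi_index)]
    networks = atlas.networks(config.modality)
    net_code = {n: i for i, n in enumerate(networks)}
    roi_net = np.array(
        [net_code[atlas.by_index(i).network] for i in roi_indices], dtype=np.int64
    )
    n_roi, n_net = len(roi_indices), len(networks)

    base = np.asarray(config.class_base_means, dtype=float)
    a = rng.normal(0.0, config.network_effect_sd, size=(3, n_net))
    b = rng.normal(0.0, config.roi_effect_sd, size=(3, n_roi))
    cell_means = base[:, None] + a[:, roi_net] + b  # (3, U)

    n_total = sum(config.n_per_group)
    class_probs = np.asarray(config.n_per_group, dtype=float) / n_total

    sigma_log = config.interval_spread_days / config.interval_median
    measures: list[LongitudinalMeasure] = []
    subj_counter = 0
    for d, (diag, n_subj) in enumerate(zip(DIAGNOSES, config.n_per_group)):
        for _ in range(n_subj):
            subj_counter += 1
            sid = f"S{subj_counter:04d}"
            interval = float(
                rng.lognormal(np.log(config.interval_median), sigma_log)
            )
            dt_years = interval / 365.25
            rates = rng.normal(cell_means[d], config.within_cell_sd)
            baselines = rng.lognormal(
                np.log(config.baseline_location),
                config.baseline_sd / config.baseline_location,
                size=n_roi,
            )
            # back-compute follow-up so the relative annualized rate is exact
            signed = rates if config.modality == TAU_SUVR else -rates
            followups = baselines * (1.0 + signed * dt_years)
            bad = followups <= 0
            if np.any(bad):
                # rare with sane settings: clamp the rate to keep scans positive
                signed = np.where(bad, -0.99 / dt_years, signed)
                followups = baselines * (1.0 + signed * dt_years)
            for r in range(n_roi):
                measures.append(
                    LongitudinalMeasure(
                        subject_id=sid,
                        diagnosis=diag,
                        roi_index=roi_indices[r],
                        modality=config.modality,
                        baseline=float(baselines[r]),
                        followup=float(followups[r]),
                        interval_days=interval,
                    )
                )

    truth = GroundTruth(
        modality=config.modality,
        roi_indices=roi_indices,
        networks=networks,
        class_probs=class_probs,
        base_means=base,
        network_shifts=a,
        roi_shifts=b,
        cell_means=cell_means,
        within_cell_sd=config.within_cell_sd,
        extras={"seed": config.seed, "n_per_group": list(config.n_per_group)},
    )
    return measures, truth


def measures_to_frame(measures: list[LongitudinalMeasure]) -> pd.DataFrame:
    """Tabulate measures in the canonical CSV schema (roi_index variant)."""
    return pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in measures],
            "diagnosis": [m.diagnosis for m in measures],
            "roi_index": [m.roi_index for m in measures],
            "modality": [m.modality for m in measures],
            "baseline": [m.baseline for m in measures],
            "followup": [m.followup for m in measures],
            "interval_days": [m.interval_days for m in measures],
        }
    )
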
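"""Relative annualized rates of change and the long-format observation table.

The predictor fed to every classification model is the relative annualized
rate of change of a region's measurement between two scans: the annualized
difference divided by the baseline value, sign-flipped for cortical
thickness so that thinning is positive. Rates are rescaled to [-1, 1] by
the per-modality maximum absolute value before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import CORTICAL_THICKNESS, TAU_SUVR, AtlasMap, Modality

__all__ = [
    "DAYS_PER_YEAR",
    "DIAGNOSES",
    "LongitudinalMeasure",
    "ObservationTable",
    "annualized_rate",
    "relative_rate_suvr",
    "relative_rate_thickness",
    "relative_rate",
    "normalize_rates",
    "assemble_observations",
    "read_measures_csv",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: Diagnostic categories; the first is the reference category of the models.
DIAGNOSES: tuple[str, ...] = ("CN", "MCI", "AD")


@dataclass(frozen=True)
class LongitudinalMeasure:
    """One (subject, ROI) scan pair for a single modality."""

    subject_id: str
    diagnosis: str
    roi_index: int
    modality: Modality
    baseline: float
    followup: float
    interval_days: float


def annualized_rate(baseline: float, followup: float, interval_days: float) -> float:
    """Annualized change: (followup - baseline) per year of inter-scan interval."""
    interval_days = np.asarray(interval_days, dtype=float)
    if np.any(interval_days <= 0):
        raise ValueError("interval_days must be positive for a valid scan pair")
    return (np.asarray(followup, float) - np.asarray(baseline, float)) / (
        interval_days / DAYS_PER_YEAR
    )


def relative_rate_suvr(baseline: float, followup: float, interval_days: float) -> float:
    """Relative annualized rate of change of SUVR (annualized rate / baseline)."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline SUVR must be positive")
    return annualized_rate(baseline, followup, interval_days) / baseline


def relative_rate_thickness(
    baseline: float, followup: float, interval_days: float
) -> float:
    """Relative annualized rate of cortical thickness change, thinning positive."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline thickness must be positive")
    return -annualized_rate(baseline, followup, interval_days) / baseline


def relative_rate(
    baseline: float, followup: float, interval_days: float, modality: Modality
) -> float:
    if modality == TAU_SUVR:
        return relative_rate_suvr(baseline, followup, interval_days)
    if modality == CORTICAL_THICKNESS:
        return relative_rate_thickness(baseline, followup, interval_days)
    raise ValueError(f"unknown modality {modality!r}")


def normalize_rates(rates: Sequence[float]) -> tuple[np.ndarray, float]:
    """Scale rates into [-1, 1] by the maximum absolute value.

    Returns the scaled array and the scale factor; multiplying the scaled
    values by the scale recovers the inputs.
    """
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty rate collection")
    if not np.all(np.isfinite(arr)):
        raise ValueError("rates must be finite")
    scale = float(np.max(np.abs(arr)))
    if scale == 0.0:
        raise ValueError("all rates are zero; normalization scale is undefined")
    return arr / scale, scale


@dataclass
class ObservationTable:
    """Long-format observation table consumed by the models.

    ``frame`` has one row per (subject, ROI) with columns ``subject_id,
    diagnosis, roi_index, network, x_raw, x_norm``. ``scale`` is the
    max-absolute-value normalization factor (x_raw = scale * x_norm).
    """

    frame: pd.DataFrame
    modality: Modality
    scale: float
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    def design_arrays(self, atlas: AtlasMap):
        """Integer-coded arrays for model fitting.

        Returns ``(y, x, u, v, roi_levels, network_levels)`` where ``y`` codes
        the diagnosis (0=CN reference, 1=MCI, 2=AD), ``x`` is the normalized
        predictor and ``u``/``v`` are 0-based ROI and network codes against
        the returned level lists.
        """
        roi_levels = atlas.roi_indices(self.modality)
        network_levels = atlas.networks(self.modality)
        roi_code = {idx: i for i, idx in enumerate(roi_levels)}
        net_code = {name: i for i, name in enumerate(network_levels)}
        y = (
            self.frame["diagnosis"]
            .map({d: i for i, d in enumerate(DIAGNOSES)})
            .to_numpy(dtype=np.int64)
        )
        x = self.frame["x_norm"].to_numpy(dtype=float)
        u = self.frame["roi_index"].map(roi_code).to_numpy(dtype=np.int64)
        v = self.frame["network"].map(net_code).to_numpy(dtype=np.int64)
        return y, x, u, v, roi_levels, network_levels

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["modality"] = self.modality
        out["scale"] = self.scale
        out.to_csv(path, index=False)


def assemble_observations(
    measures: Sequence[LongitudinalMeasure],
    atlas: AtlasMap,
    modality: Modality,
) -> ObservationTable:
    """Join rates to the atlas and build the model-ready observation table.

    Measures with a missing baseline or follow-up value are dropped with a
    logged warning; unknown diagnosis labels or ROI indices raise.
    """
    rows = []
    n_dropped = 0
    for m in measures:
        if m.modality != modality:
            continue
        if m.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis label {m.diagnosis!r}")
        rec = atlas.by_index(m.roi_index)  # raises on unknown ROI
        if modality == CORTICAL_THICKNESS and not rec.cortical:
            raise ValueError(
                f"subcortical ROI {m.roi_index} is not valid for cortical thickness"
            )
        if (
            m.baseline is None
            or m.followup is None
            or not np.isfinite(m.baseline)
            or not np.isfinite(m.followup)
        ):
            n_dropped += 1
            continue
        x_raw = float(relative_rate(m.baseline, m.followup, m.interval_days, modality))
        rows.append((m.subject_id, m.diagnosis, m.roi_index, rec.network, x_raw))

    if n_dropped:
        logger.warning(
            "dropped %d measure(s) with missing baseline/follow-up", n_dropped
        )
    if not rows:
        raise ValueError("no usable measures for the requested modality")

    frame = pd.DataFrame(
        rows, columns=["subject_id", "diagnosis", "roi_index", "network", "x_raw"]
    )
    x_norm, scale = normalize_rates(frame["x_raw"].to_numpy())
    frame["x_norm"] = x_norm
    return ObservationTable(
        frame=frame, modality=modality, scale=scale, n_dropped=n_dropped
    )


_CSV_COLUMNS = [
    "subject_id",
    "diagnosis",
    "roi_label",
    "hemisphere",
    "modality",
    "baseline",
    "followup",
    "interval_days",
]


def read_measures_csv(path, atlas: AtlasMap) -> list[LongitudinalMeasure]:
    """Read scan-pair measures from the canonical CSV schema.

    Expected header: ``subject_id, diagnosis, roi_label, hemisphere, modality,
    baseline, followup, interval_days``. A ``roi_index`` column may replace
    the label/hemisphere pair.
    """
    df = pd.read_csv(path)
    has_index = "roi_index" in df.columns
    required = set(_CSV_COLUMNS) - ({"roi_label", "hemisphere"} if has_index else set())
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measures CSV is missing columns: {sorted(missing)}")

    measures = []
    for row in df.itertuples(index=False):
        if has_index:
            roi_index = int(row.roi_index)
        else:
            roi_index = atlas.lookup(row.roi_label, row.hemisphere).roi_index
        measures.append(
            LongitudinalMeasure(
                subject_id=str(row.subject_id),
                diagnosis=str(row.diagnosis),
                roi_index=roi_index,
                modality=str(row.modality),  # type: ignore[arg-type]
                baseline=float(row.baseline),
                followup=float(row.followup),
                interval_days=float(row.interval_days),
            )
        )
    return measures
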
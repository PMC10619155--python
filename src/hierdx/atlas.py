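"""ROI atlas: region labels, hemispheres, functional networks and Braak stages.

The packaged table transcribes the right-hemisphere ROI/network/Braak map
(38 regions: 31 cortical + 7 subcortical). :func:`build_atlas` mirrors it to
both hemispheres, giving 76 bilateral regions for tau-PET and 62 cortical
regions for cortical thickness. Subcortical regions form their own network
cluster in addition to the seven cortical resting-state networks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "RoiRecord",
    "AtlasMap",
    "build_atlas",
    "CORTICAL_NETWORKS",
    "SUBCORTICAL_NETWORK",
    "TAU_SUVR",
    "CORTICAL_THICKNESS",
]

Hemisphere = Literal["left", "right"]
Modality = Literal["tau_suvr", "cortical_thickness"]

TAU_SUVR: Modality = "tau_suvr"
CORTICAL_THICKNESS: Modality = "cortical_thickness"

#: The seven cortical resting-state networks, in a fixed canonical order.
CORTICAL_NETWORKS: tuple[str, ...] = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "Salience/VentralAttention",
    "Limbic",
    "Control",
    "DefaultMode",
)

#: Extra network cluster holding all subcortical regions (tau-PET only).
SUBCORTICAL_NETWORK = "Subcortical"

#: Number of regions per hemisphere in the packaged map.
_N_PER_HEMI = 38


@dataclass(frozen=True)
class RoiRecord:
    """One hemisphere-specific region of interest."""

    roi_label: str
    roi_abbrev: str
    hemisphere: Hemisphere
    roi_index: int
    network: str
    braak_stage: int | None
    cortical: bool

    def __post_init__(self) -> None:
        if self.cortical:
            if self.network not in CORTICAL_NETWORKS:
                raise ValueError(
                    f"cortical ROI {self.roi_label!r} must map to one of the "
                    f"seven cortical networks, got {self.network!r}"
                )
        elif self.network != SUBCORTICAL_NETWORK:
            raise ValueError(
                f"subcortical ROI {self.roi_label!r} must map to "
                f"{SUBCORTICAL_NETWORK!r}, got {self.network!r}"
            )
        if self.braak_stage is not None and not 1 <= self.braak_stage <= 6:
            raise ValueError(f"braak_stage must be in 1..6, got {self.braak_stage}")
        if self.roi_index < 1:
            raise ValueError("roi_index must be >= 1")


class AtlasMap:
    """Bilateral ROI -> (hemisphere, network, Braak stage) map."""

    def __init__(self, records: Iterable[RoiRecord]):
        self._records: list[RoiRecord] = list(records)
        self._by_index: dict[int, RoiRecord] = {}
        self._by_label: dict[tuple[str, str], RoiRecord] = {}
        for rec in self._records:
            if rec.roi_index in self._by_index:
                raise ValueError(f"duplicate roi_index {rec.roi_index}")
            key = (rec.roi_label.lower(), rec.hemisphere)
            if key in self._by_label:
                raise ValueError(
                    f"duplicate ROI label {rec.roi_label!r} ({rec.hemisphere})"
                )
            self._by_index[rec.roi_index] = rec
            self._by_label[key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def lookup(self, roi_label: str, hemisphere: Hemisphere) -> RoiRecord:
        """Look a region up by its label and hemisphere."""
        try:
            return self._by_label[(roi_label.lower(), hemisphere)]
        except KeyError:
            raise KeyError(f"unknown ROI {roi_label!r} ({hemisphere})") from None

    def by_index(self, roi_index: int) -> RoiRecord:
        try:
            return self._by_index[roi_index]
        except KeyError:
            raise KeyError(f"unknown roi_index {roi_index}") from None

    def records(self, modality: Modality = TAU_SUVR) -> list[RoiRecord]:
        """All records available for a modality (cortical only for thickness)."""
        _check_modality(modality)
        if modality == CORTICAL_THICKNESS:
            return [r for r in self._records if r.cortical]
        return list(self._records)

    def roi_indices(self, modality: Modality = TAU_SUVR) -> list[int]:
        return sorted(r.roi_index for r in self.records(modality))

    def networks(self, modality: Modality = TAU_SUVR) -> list[str]:
        """Distinct network clusters for a modality, in canonical order."""
        present = {r.network for r in self.records(modality)}
        order = CORTICAL_NETWORKS + (SUBCORTICAL_NETWORK,)
        return [n for n in order if n in present]

    def n_rois(self, modality: Modality = TAU_SUVR) -> int:
        return len(self.records(modality))

    def n_networks(self, modality: Modality = TAU_SUVR) -> int:
        return len(self.networks(modality))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_index": [r.roi_index for r in self._records],
                "roi_label": [r.roi_label for r in self._records],
                "roi_abbrev": [r.roi_abbrev for r in self._records],
                "hemisphere": [r.hemisphere for r in self._records],
                "network": [r.network for r in self._records],
                "braak_stage": [r.braak_stage for r in self._records],
                "cortical": [r.cortical for r in self._records],
            }
        )


def _check_modality(modality: str) -> None:
    if modality not in (TAU_SUVR, CORTICAL_THICKNESS):
        raise ValueError(f"unknown modality {modality!r}")


def _packaged_table() -> pd.DataFrame:
    with importlib.resources.files("hierdx.data").joinpath(
        "roi_network_map.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def build_atlas(source: str | pd.DataFrame | None = None) -> AtlasMap:
    """Build the bilateral atlas from a single-hemisphere map.

    Parameters
    ----------
    source
        A CSV path or DataFrame with columns ``roi_index, roi_label,
        roi_abbrev, network, braak_stage, cortical`` describing one
        hemisphere. Defaults to the packaged 38-region transcription.

    Returns
    -------
    AtlasMap
        Right-hemisphere regions keep their table indices; left-hemisphere
        mirrors are offset by the per-hemisphere region count, so every
        bilateral region has a unique index.
    """
    if source is None:
        table = _packaged_table()
    elif isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source)

    if table["roi_label"].duplicated().any():
        dupes = table.loc[table["roi_label"].duplicated(), "roi_label"].tolist()
        raise ValueError(f"duplicate ROI labels in source table: {dupes}")

    n = len(table)
    records: list[RoiRecord] = []
    for hemi, offset in (("right", 0), ("left", n)):
        for row in table.itertuples(index=False):
            stage = row.braak_stage
            stage = None if pd.isna(stage) else int(stage)
            records.append(
                RoiRecord(
                    roi_label=str(row.roi_label),
                    roi_abbrev=str(row.roi_abbrev),
                    hemisphere=hemi,  # type: ignore[arg-type]
                    roi_index=int(row.roi_index) + offset,
                    network=str(row.network),
                    braak_stage=stage,
                    cortical=bool(row.cortical),
                )
            )
    return AtlasMap(records)
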
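"""High-level glue: fit a numbered model to an observation table."""

from __future__ import annotations

from .atlas import AtlasMap
from .models import PriorConfig, structure_for_model
from .rates import ObservationTable
from .sampler import PosteriorDraws, SamplerConfig, sample_posterior

__all__ = ["fit_model"]


def fit_model(
    model: int,
    obs: ObservationTable,
    atlas: AtlasMap,
    priors: PriorConfig | None = None,
    config: SamplerConfig | None = None,
    store_log_lik: bool = True,
) -> PosteriorDraws:
    """Fit model 1-4 to an assembled observation table.

    The fit's metadata records the modality, normalization scale and the
    ROI/network level maps so that prediction curves can be drawn in raw
    units later without re-reading the data.
    """
    y, x, u, v, roi_levels, network_levels = obs.design_arrays(atlas)
    structure = structure_for_model(model, len(roi_levels), len(network_levels))
    meta = {
        "model": model,
        "modality": obs.modality,
        "scale": obs.scale,
        "roi_levels": roi_levels,
        "network_levels": network_levels,
        "roi_networks": [atlas.by_index(i).network for i in roi_levels],
    }
    return sample_posterior(
        structure,
        priors or PriorConfig(),
        y,
        x,
        u,
        v,
        config=config,
        meta=meta,
        store_log_lik=store_log_lik,
    )
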
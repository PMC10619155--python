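import numpy as np
import pytest

from hierdx.atlas import build_atlas
from hierdx.cohort import CohortConfig, reduced_atlas, simulate_cohort
from hierdx.models import PriorConfig
from hierdx.rates import assemble_observations
from hierdx.sampler import SamplerConfig
from hierdx.workflow import fit_model


@pytest.fixture(scope="session")
def atlas():
    return build_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    """12 bilateral ROIs across 4 networks."""
    return reduced_atlas(6, 4)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """30-subject cohort on the small atlas, with moderate group separation."""
    config = CohortConfig(
        n_per_group=(10, 10, 10),
        atlas=small_atlas,
        seed=42,
        class_base_means=(0.0, 0.05, 0.10),
        network_effect_sd=0.04,
        roi_effect_sd=0.01,
        within_cell_sd=0.15,
    )
    measures, truth = simulate_cohort(config)
    obs = assemble_observations(measures, small_atlas, "tau_suvr")
    return config, obs, truth


#: Priors wide enough that reduced-scale synthetic coefficients (order 1)
#: are dominated by the likelihood; the default scales target the
#: normalized real data, not the synthetic recovery regime.
WIDE_PRIORS = PriorConfig().scaled(10.0)


@pytest.fixture(scope="session")
def wide_priors():
    return WIDE_PRIORS


@pytest.fixture(scope="session")
def model4_fit_default(small_cohort, small_atlas):
    """Model 4 under the default sampler configuration (shared by the
    sampler-health acceptance checks; ~1 min)."""
    _, obs, _ = small_cohort
    return fit_model(
        4, obs, small_atlas, priors=WIDE_PRIORS, config=SamplerConfig(seed=2024)
    )


@pytest.fixture(scope="session")
def model1_toy_fit():
    """Small complete-pooling fit on separable toy data (fast, reusable)."""
    rng = np.random.default_rng(7)
    n = 120
    y = rng.integers(0, 3, n)
    x = rng.normal(0.3 * (y - 1), 0.6, n).clip(-1, 1)
    from hierdx.models import structure_for_model
    from hierdx.sampler import sample_posterior

    structure = structure_for_model(1, 1, 1)
    fit = sample_posterior(
        structure,
        WIDE_PRIORS,
        y,
        x,
        config=SamplerConfig(n_iterations_per_chain=600, n_warmup=300, seed=5),
        meta={"modality": "tau_suvr", "scale": 1.0},
    )
    return y, x, fit
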
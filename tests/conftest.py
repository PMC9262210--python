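import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from sibige import (
    CohortConfig,
    EffectParams,
    TraitConfig,
    assign_strata,
    simulate_cohort,
)

COVARIATES = ["sex", "birth_year"] + [f"pc{i}" for i in range(1, 11)]


@pytest.fixture(scope="session")
def ige_cohort():
    """Mid-sized labelled cohort with an all-sibling IGE on one trait."""
    config = CohortConfig(
        n_individuals=60_000,
        traits=(
            TraitConfig("ea", EffectParams(k_I=0.5, k_M=0.1, k_P=0.1, k_S=0.2)),
            TraitConfig("height", EffectParams(k_I=0.6)),
        ),
        seed=42,
    )
    return assign_strata(simulate_cohort(config))


@pytest.fixture(scope="session")
def null_cohort():
    """Labelled cohort with no sibling IGE (null calibration)."""
    config = CohortConfig(
        n_individuals=60_000,
        traits=(TraitConfig("ea", EffectParams(k_I=0.5, k_M=0.1, k_P=0.1)),),
        seed=43,
    )
    return assign_strata(simulate_cohort(config))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
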
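import dataclasses

import pytest

from moltstage.config import CohortConfig, NoiseSD
from moltstage.study import milestone_recovery_study


@pytest.fixture
def paper_like_config() -> CohortConfig:
    """Default cohort: 14 nymphs, daily sampling from day 4, moderate noise."""
    return CohortConfig()


@pytest.fixture
def zero_noise_config() -> CohortConfig:
    """Noiseless cohort with a common ecdysis day (analytic ground truth)."""
    return CohortConfig(
        noise_sd=NoiseSD(weight=0.0, iw=0.0, ecdysteroid=0.0),
        instar_duration_sd=0.0,
    )


@pytest.fixture(scope="session")
def recovery_study_200():
    """200 paper-like replicate cohorts fitted with true-SEM weighting.

    Shared between the coverage check and the simulation-study acceptance
    test; computed once per session.
    """
    config = CohortConfig()
    study = milestone_recovery_study(config, 200, seed=202, weighting="true")
    return config, study
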
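import numpy as np
import pytest

from poppk import CohortConfig, default_quetiapine_model, generate_cohort


@pytest.fixture(scope="session")
def ref_model():
    return default_quetiapine_model()


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects, mixed sampling, boosted DDI prevalence."""
    return generate_cohort(CohortConfig(
        n_subjects=12, obs_per_subject=2, flu_prevalence=0.25,
        dul_prevalence=0.25, sampling="mixed", seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
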
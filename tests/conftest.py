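import numpy as np
import pytest

from eegrisk.pipeline import cohort_feature_matrix, preprocess_cohort
from eegrisk.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_subjects=4, recording_length=120.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_feature_matrix(small_cohort):
    return cohort_feature_matrix(preprocess_cohort(small_cohort))


@pytest.fixture(scope="session")
def study_config() -> CohortConfig:
    """The default study conditions: 20 subjects, 600 s each."""
    return CohortConfig(n_subjects=20, recording_length=600.0, seed=7)


@pytest.fixture(scope="session")
def study_feature_matrix(study_config):
    """Full-pipeline feature matrix at study scale (built once per session)."""
    cohort = generate_cohort(study_config)
    return cohort_feature_matrix(preprocess_cohort(cohort))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
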
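import numpy as np
import pytest

from mbssm.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """Small paired cohort for fast unit tests: 12 subjects, 40/36 points."""
    return SyntheticCohortSpec(
        n_subjects=12,
        m_per_body={"scapula": 40, "humerus": 36},
        q_shared=3,
        q_own=3,
        coupling_fraction=0.5,
        noise_sd=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    cohort, _ = generate_cohort(small_spec)
    return cohort


@pytest.fixture(scope="session")
def small_record(small_spec):
    _, record = generate_cohort(small_spec)
    return record


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
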
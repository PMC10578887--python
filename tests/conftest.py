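import numpy as np
import pytest

from tridem.synthetic_cohort import CohortGeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A medium synthetic cohort with default (realistic-overlap) settings."""
    return generate_cohort(CohortGeneratorConfig(n_subjects=600, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
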
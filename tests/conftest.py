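import numpy as np
import pytest

from ptsdpipe.synthetic_cohort import (
    CohortConfig,
    apply_validity_filter,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """Full default cohort at seed 1, shared across tests (read-only)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def valid_respondents(default_cohort):
    valid, _ = apply_validity_filter(default_cohort)
    return valid


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
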
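import numpy as np
import pytest

from bitrl import default_config, simulate_cohort


@pytest.fixture(scope="session")
def task():
    return default_config()


@pytest.fixture(scope="session")
def kl_cohort_small():
    """Six KL-generated subjects, 60 trials each (shared across tests)."""
    return simulate_cohort(6, model="kl", randomness=42)


@pytest.fixture(scope="session")
def rw_cohort_small():
    return simulate_cohort(6, model="rw", randomness=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
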
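import numpy as np
import pytest

from cogcap.mft import default_design
from cogcap.simulate import PopulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-subject clean cohort shared by read-only tests."""
    return simulate_cohort(PopulationConfig(n_subjects=25, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
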
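import numpy as np
import pytest
from hypothesis import settings

from mirsite.synthetic_data import SimConfig, gen_cohort

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return gen_cohort(SimConfig(seed=1))
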
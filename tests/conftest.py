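import numpy as np
import pytest
from hypothesis import settings

from scmetseq import SimConfig, toy_grid

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    """Small two-chromosome grid (2 x 50 bins of 500 kb)."""
    return toy_grid()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240206)
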
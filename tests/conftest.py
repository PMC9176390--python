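import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from periphdose.conversion import load_hstar, load_qk
from periphdose.spectra import make_log_grid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    """Default 1 meV – 200 MeV grid at 10 bins per decade (114 bins)."""
    return make_log_grid()


@pytest.fixture(scope="session")
def qk_table():
    return load_qk()


@pytest.fixture(scope="session")
def hstar_table():
    return load_hstar()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
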
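import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glycounmix as g

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return g.default_library()


@pytest.fixture(scope="session")
def analysis_grid():
    return g.fingerprint_grid()  # 1000-1150, 2 cm^-1, 76 bins


@pytest.fixture(scope="session")
def raw_grid():
    return g.WavenumberGrid(1000, 1150, 0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
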
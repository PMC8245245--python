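import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import mupool as mp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return mp.PoolConfig()


@pytest.fixture(scope="session")
def default_pool(default_cfg):
    return mp.build_pool(default_cfg)


@pytest.fixture(scope="session")
def small_pool():
    """12-unit / 700-fiber pool: same generative rules, fast to simulate."""
    return mp.make_fixture_pool()


@pytest.fixture(scope="session")
def small_geometry():
    return mp.MuscleGeometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
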
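import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aodgp.grids import GridSpec
from aodgp.synth import TruthParams, generate_day

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid10() -> GridSpec:
    """100 x 100 cells of 0.1 degrees: the standard synthetic study domain."""
    return GridSpec(105.0, 115.0, 25.0, 35.0, 0.1)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(110.0, 112.0, 30.0, 32.0, 0.1)


@pytest.fixture(scope="session")
def default_truth() -> TruthParams:
    return TruthParams()


@pytest.fixture(scope="session")
def day200(grid10, default_truth):
    """One synthetic day with 200 sites under the default truth."""
    return generate_day(grid10, 200, default_truth, seed=11)


@pytest.fixture(scope="session")
def day60(grid10, default_truth):
    return generate_day(grid10, 60, default_truth, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
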
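import numpy as np
import pytest

from filoguide import Grating, GrowthConeDisk, GuidanceParams, SimParams


@pytest.fixture(scope="session")
def period1() -> Grating:
    """The reference nanograting: 500 nm ridges/grooves, 250 nm deep."""
    return Grating(ridge_width=0.5, groove_width=0.5, ridge_depth=0.25)


@pytest.fixture(scope="session")
def guidance() -> GuidanceParams:
    return GuidanceParams()


@pytest.fixture()
def sim_params() -> SimParams:
    return SimParams(seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def disk_factory():
    def make(y: float, radius: float = 1.14) -> GrowthConeDisk:
        return GrowthConeDisk((0.0, y), radius)

    return make
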
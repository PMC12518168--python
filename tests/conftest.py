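import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from urbanhab import GridHeader

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def header10() -> GridHeader:
    return GridHeader(ncols=10, nrows=10, xll=102.0, yll=25.0, cellsize=0.01)


@pytest.fixture
def header100() -> GridHeader:
    return GridHeader(ncols=100, nrows=100, xll=102.0, yll=25.0, cellsize=0.01)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
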
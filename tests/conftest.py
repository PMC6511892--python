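import numpy as np
import pytest

from classa.preprocess import UniformHRV
from classa.simulate import fixture_library


@pytest.fixture(scope="session")
def fixtures():
    return fixture_library()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def hrv(values, rate=4.0, start=0.0):
    """Shorthand for building a UniformHRV from raw values."""
    return UniformHRV(np.asarray(values, dtype=float), rate=rate, start_time=start)


@pytest.fixture
def make_hrv():
    return hrv
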
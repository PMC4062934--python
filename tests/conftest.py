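import numpy as np
import pytest

from petalpol import synthetic_scene as ss


@pytest.fixture(scope="session")
def contrast_pattern():
    return ss.make_target_pattern("contrast")


@pytest.fixture(scope="session")
def plain_pattern():
    return ss.make_target_pattern("plain")


@pytest.fixture(scope="session")
def noiseless_config():
    return ss.AcquisitionConfig()


@pytest.fixture(scope="session")
def small_pattern():
    """A reduced-scale contrast target for tests where geometry is incidental."""
    return ss.make_target_pattern("contrast", px_per_mm=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
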
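import numpy as np
import pytest

from serspls.synth import DEFAULT_AXIS_SPEC, NoiseConfig, build_axis, default_libraries


@pytest.fixture(scope="session")
def axis():
    return build_axis(*DEFAULT_AXIS_SPEC)


@pytest.fixture(scope="session")
def libraries():
    return default_libraries()


@pytest.fixture
def zero_noise():
    return NoiseConfig.zero()


@pytest.fixture
def repro_noise():
    return NoiseConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
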
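import numpy as np
import pytest

from opmbeta.geometry import HeadModel, make_sensor_array


@pytest.fixture(scope="session")
def small_array():
    return make_sensor_array(16, head_radius=0.08, scalp_offset=0.01, seed=7)


@pytest.fixture(scope="session")
def head():
    return HeadModel(sphere_radius=0.08)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
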
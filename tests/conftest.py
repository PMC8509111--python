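import numpy as np
import pytest
from hypothesis import settings

from spframe.config import FrameConfig
from spframe.geometry import build_frame

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sp3_frame():
    return FrameConfig.sp3()


@pytest.fixture(scope="session")
def sp4_frame():
    return FrameConfig.sp4()


@pytest.fixture(scope="session")
def n4_frame():
    return FrameConfig.n4()


@pytest.fixture(scope="session")
def sp3_geoms(sp3_frame):
    return build_frame(sp3_frame)


@pytest.fixture(scope="session")
def sp4_geoms(sp4_frame):
    return build_frame(sp4_frame)


@pytest.fixture(scope="session")
def n4_geoms(n4_frame):
    return build_frame(n4_frame)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
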
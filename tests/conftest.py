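import numpy as np
import pytest

from gonadsim.profiles import CellCycleProfile, MZGeometry
from gonadsim.synthetic_data import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_profile():
    return CellCycleProfile.flat(2.8)


@pytest.fixture
def small_geometry():
    return MZGeometry.rectangular(5, 4)
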
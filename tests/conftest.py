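import numpy as np
import pytest

from loopsmooth.fixtures import FixtureConfig, generate_fixture
from loopsmooth.simulate import SimulationSetting, simulate_setting
from loopsmooth.tracks import PositionTrack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sine_track():
    l = np.arange(4000)
    return PositionTrack("chr1", 1, np.sin(2 * np.pi * l / 10.4))


@pytest.fixture(scope="session")
def setting_i_small():
    """A modest setting-(i) simulation shared by non-acceptance tests."""
    return simulate_setting(SimulationSetting("i", length=20_000, seed=7))


@pytest.fixture(scope="session")
def fixture_data():
    """The default synthetic dataset (genome, tracks, dyads, library)."""
    return generate_fixture(FixtureConfig(seed=0))
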
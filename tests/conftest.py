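import numpy as np
import pytest

import mcgkit as m


@pytest.fixture(scope="session")
def geometry():
    """Default 64-channel planar array."""
    return m.planar_grid()


@pytest.fixture(scope="session")
def small_geometry():
    """Compact 16-channel array for cheap signal-chain tests."""
    return m.planar_grid(4, 0.04)


@pytest.fixture(scope="session")
def default_source():
    return m.DipoleSource(position=[0.0, 0.0, -0.08], moment_direction=[1.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def default_beat(geometry, default_source):
    """One noiseless beat of the default template on the full array."""
    return m.synthesize_beat(m.BeatTemplate(), default_source, geometry)


@pytest.fixture(scope="session")
def small_beat(small_geometry, default_source):
    return m.synthesize_beat(m.BeatTemplate(), default_source, small_geometry)


@pytest.fixture(scope="session")
def study_table():
    """Feature cohort drawn from the packaged study scenario (70/69/37)."""
    return m.sample_feature_cohort(m.study_scenario(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
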
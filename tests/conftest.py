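import numpy as np
import pytest

from mobilitykit.geo import unproject_aeqd
from mobilitykit.gps import GpsTrack
from mobilitykit.synth import ScenarioConfig

HOME = (43.26, -79.92)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_config():
    return ScenarioConfig(seed=7, gps_noise_sd_m=0.0, dropout_prob=0.0,
                          accel_noise_sd_g=0.0)


def track_from_xy(t, x, y, home=HOME, device="test", speed=None):
    """Build a GpsTrack from local-plane meters around HOME."""
    lat, lon = unproject_aeqd(np.asarray(x, float), np.asarray(y, float), *home)
    return GpsTrack(np.asarray(t, float), np.atleast_1d(lat), np.atleast_1d(lon),
                    speed, device)
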
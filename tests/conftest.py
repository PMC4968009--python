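import numpy as np
import pytest

from movelsp import MovementModelSpec, TrackSeries, simulate_batch

HOUR = 3600.0
DAY = 86400.0


@pytest.fixture
def rng():
    return np.random.default_rng(20160801)


@pytest.fixture
def hourly_times():
    def make(n):
        return np.arange(n) * HOUR

    return make


@pytest.fixture
def ou_track(hourly_times):
    """Medium OU track used by several spectral tests."""
    times = hourly_times(512)
    spec = MovementModelSpec("OU", 100.0, tau_pos=10 * HOUR)
    coords = simulate_batch(spec, times, k=2, seed=11)[0]
    return TrackSeries("ou", times, coords)
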
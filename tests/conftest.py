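import numpy as np
import pytest

from placecode.core import SessionSchedule, SpikeTrain, Trajectory
from placecode.maps import RateMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line_trajectory():
    """Back-and-forth motion at a constant 10 cm/s along x for 60 s at 50 Hz
    (triangle wave between -29 and +29 cm, staying inside the arena)."""
    t = np.arange(0, 60, 0.02)
    period = 4 * 29.0 / 10.0  # out and back
    phase = np.mod(t, period) / period
    tri = 2 * np.abs(2 * phase - 1) - 1  # in [-1, 1], slope magnitude constant
    return Trajectory(timestamps=t, x=29.0 * tri, y=np.zeros_like(t),
                      arena_radius=31.0)


@pytest.fixture
def stationary_trajectory():
    t = np.arange(0, 60, 0.02)
    return Trajectory(timestamps=t, x=np.full_like(t, 5.0),
                      y=np.full_like(t, -3.0), arena_radius=31.0)


def four_bin_map(rates, occupancy=None):
    """Minimal 2x2 rate map with the given per-bin rates (row-major)."""
    rates = np.asarray(rates, float).reshape(2, 2)
    occ = (np.full((2, 2), 1.0) if occupancy is None
           else np.asarray(occupancy, float).reshape(2, 2))
    valid = np.ones((2, 2), dtype=bool)
    counts = (rates > 0).astype(float)
    return RateMap(bin_size=2.5, occupancy=occ, smoothed_rate=rates,
                   valid_mask=valid, spike_counts=counts)


@pytest.fixture
def schedule():
    return SessionSchedule(day=1, session_in_day=1)


def train_ms(times_ms, **kw):
    """SpikeTrain from spike times given in milliseconds."""
    return SpikeTrain(cluster_id=kw.pop("cluster_id", "c"),
                      spike_times=np.asarray(times_ms, float) / 1000.0, **kw)
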
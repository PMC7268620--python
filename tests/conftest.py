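import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from nestfate import SimScenario, Track, simulate_track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(lons, lats, start="2021-04-01T08:00:00Z", step_minutes=60, track_id="t1"):
    """Small hand-built track with evenly spaced timestamps."""
    n = len(lons)
    times = pd.date_range(start, periods=n, freq=f"{step_minutes}min", tz="UTC")
    return Track(id=track_id, times=times, lon=np.asarray(lons, float), lat=np.asarray(lats, float))


def random_cluster_track(rng, n_fixes=200, n_days=10, scatter_m=60.0, track_id="rnd"):
    """Random mid-latitude track with clustered structure at buffer scale."""
    lat0 = float(rng.uniform(-60, 60))
    lon0 = float(rng.uniform(-170, 170))
    mpd_lat = 111_000.0
    mpd_lon = 111_000.0 * np.cos(np.radians(lat0))
    k = int(rng.integers(1, 6))
    cx = rng.normal(0, 500, k)
    cy = rng.normal(0, 500, k)
    which = rng.integers(0, k, n_fixes)
    x = cx[which] + rng.normal(0, scatter_m, n_fixes)
    y = cy[which] + rng.normal(0, scatter_m, n_fixes)
    day = rng.integers(0, n_days, n_fixes)
    minute = rng.integers(6 * 60, 20 * 60, n_fixes)
    times = pd.DatetimeIndex(
        pd.to_datetime("2021-04-01", utc=True) + pd.to_timedelta(day * 24 * 60 + minute, unit="m")
    )
    order = np.argsort(times.asi8, kind="stable")
    times, x, y = times[order], x[order], y[order]
    keep = np.concatenate(([True], np.diff(times.asi8) != 0))
    return Track(
        id=track_id,
        times=times[keep],
        lon=lon0 + (x[keep] / mpd_lon),
        lat=lat0 + (y[keep] / mpd_lat),
    )


@pytest.fixture
def breeder_track():
    sc = SimScenario(track_id="breeder", t_full=40, seed=11)
    return simulate_track(sc)


@pytest.fixture
def nonbreeder_track():
    from nestfate import non_breeder_scenario

    sc = non_breeder_scenario(track_id="nonbreeder", t_full=40, seed=12)
    return simulate_track(sc)
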
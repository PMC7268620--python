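"""Synthetic central-place-forager data with known ground truth.

Two generators cover the two halves of the pipeline:

* :func:`simulate_track` emits a GPS trajectory for one individual-year:
  daytime-only fix schedules at a nominal interval, random fix failures,
  Gaussian GPS scatter, daily nest attendance that may decline with nest
  age (parameterized on the logit scale, the same language as the
  estimator's p_t GLM), abrupt cessation of nest visits at a planted
  failure day, and foraging trips to a set of revisited foraging sites —
  the confounders the nest filter has to reject. Non-breeders wander
  among foraging sites only; their sites drift from day to day, as real
  non-breeding ranges do, which keeps any one 40-m buffer from being
  revisited over long runs of days.

* :func:`simulate_histories` draws daily visit records directly from the
  survival/detection model's generative equations, retaining the latent
  alive/dead paths for calibration checks.

Everything is driven by a single seed; identical scenarios give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .geo_tracks import EARTH_RADIUS_M, Track
from .survival_model import ModelParams, VisitHistory

__all__ = [
    "SimScenario",
    "simulate_track",
    "simulate_histories",
    "simulate_fate_cohort",
    "simulate_labeled_metrics",
    "SPECIES_SIM_DEFAULTS",
]

# Emulated tag programmes for the three case-study species:
# breeding-cycle length (days) and nominal fix interval (minutes).
SPECIES_SIM_DEFAULTS = {
    "stork": {"t_full": 110, "nominal_interval": 60.0},
    "kestrel": {"t_full": 60, "nominal_interval": 15.0},
    "gull": {"t_full": 60, "nominal_interval": 15.0},
}


@dataclass
class SimScenario:
    """Ground-truthed scenario for one simulated individual-year."""

    nest_lon: float = 12.0
    nest_lat: float = 44.0
    start_date: date = date(2021, 4, 1)
    fate: str = "success"  # "success" | "failure"
    failure_day: int | None = None  # 1-based; required when fate == "failure"
    t_full: int = 60
    nominal_interval: float = 60.0  # minutes
    day_start_hour: int = 6  # solar tags record primarily during daytime
    day_end_hour: int = 20
    fix_failure_rate: float = 0.1
    gps_noise_sd_m: float = 10.0
    # daily nest attendance Pr(fix at nest | alive) on the logit scale
    attendance_logit0: float = float(logit(0.9))
    attendance_logit1: float = 0.0  # per-day slope (negative = declining)
    n_foraging_sites: int = 3
    foraging_site_km: tuple[float, float] = (2.0, 10.0)  # distance range from nest
    site_stickiness: float = 0.8  # Pr(next foraging fix at same site)
    site_drift_sd_m: float = 0.0  # daily random walk of site positions
    jitter_sd_m: float = 30.0  # correlated-random-walk jitter around sites
    non_breeder: bool = False
    seed: int = 0
    track_id: str = "sim"

    def __post_init__(self) -> None:
        if self.fate not in ("success", "failure"):
            raise ValueError("fate must be 'success' or 'failure'")
        if self.fate == "failure":
            if self.failure_day is None or not (1 <= self.failure_day < self.t_full):
                raise ValueError("failure requires 1 <= failure_day < t_full")
        if not (0 <= self.fix_failure_rate <= 1):
            raise ValueError("fix_failure_rate must be a probability")


def _meters_to_deg(dx_m, dy_m, lat: float):
    dlat = np.degrees(np.asarray(dy_m) / EARTH_RADIUS_M)
    dlon = np.degrees(np.asarray(dx_m) / (EARTH_RADIUS_M * math.cos(math.radians(lat))))
    return dlon, dlat


def non_breeder_scenario(**kwargs) -> SimScenario:
    """Scenario preset for a wandering non-breeder (drifting site pool)."""
    kwargs.setdefault("non_breeder", True)
    kwargs.setdefault("site_drift_sd_m", 200.0)
    kwargs.setdefault("n_foraging_sites", 6)
    kwargs.setdefault("site_stickiness", 0.5)
    return SimScenario(**kwargs)


def simulate_track(scenario: SimScenario) -> tuple[Track, dict]:
    """Simulate one individual-year and return (track, truth record)."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    # foraging sites at random bearings/distances from the nest
    bearings = rng.uniform(0, 2 * np.pi, sc.n_foraging_sites)
    dists = rng.uniform(sc.foraging_site_km[0] * 1000, sc.foraging_site_km[1] * 1000, sc.n_foraging_sites)
    sx, sy = dists * np.cos(bearings), dists * np.sin(bearings)

    n_per_day = max(1, int((sc.day_end_hour - sc.day_start_hour) * 60 // sc.nominal_interval))
    start = pd.Timestamp(sc.start_date, tz="UTC")

    times: list[pd.Timestamp] = []
    lons: list[float] = []
    lats: list[float] = []
    cur_site = int(rng.integers(sc.n_foraging_sites))
    jx = jy = 0.0
    for d in range(sc.t_full):
        if sc.site_drift_sd_m > 0:
            sx = sx + rng.normal(0, sc.site_drift_sd_m, sc.n_foraging_sites)
            sy = sy + rng.normal(0, sc.site_drift_sd_m, sc.n_foraging_sites)
        alive = (not sc.non_breeder) and (sc.fate == "success" or (d + 1) < sc.failure_day)
        att = float(expit(sc.attendance_logit0 + sc.attendance_logit1 * (d + 1)))
        for k in range(n_per_day):
            if rng.random() < sc.fix_failure_rate:
                continue
            ts = start + pd.Timedelta(days=d, hours=sc.day_start_hour, minutes=k * sc.nominal_interval)
            at_nest = alive and (rng.random() < att)
            if at_nest:
                x, y = 0.0, 0.0
            else:
                if rng.random() > sc.site_stickiness:
                    cur_site = int(rng.integers(sc.n_foraging_sites))
                jx += rng.normal(0, sc.jitter_sd_m * 0.3)
                jy += rng.normal(0, sc.jitter_sd_m * 0.3)
                r = math.hypot(jx, jy)
                if r > sc.jitter_sd_m * 2:  # keep jitter bounded around the site
                    jx *= sc.jitter_sd_m / r
                    jy *= sc.jitter_sd_m / r
                x, y = sx[cur_site] + jx, sy[cur_site] + jy
            x += rng.normal(0, sc.gps_noise_sd_m)
            y += rng.normal(0, sc.gps_noise_sd_m)
            dlon, dlat = _meters_to_deg(x, y, sc.nest_lat)
            times.append(ts)
            lons.append(sc.nest_lon + float(dlon))
            lats.append(sc.nest_lat + float(dlat))

    track = Track(
        id=sc.track_id,
        times=pd.DatetimeIndex(times),
        lon=np.array(lons),
        lat=np.array(lats),
        nominal_interval=sc.nominal_interval,
    )
    truth = {
        "track_id": sc.track_id,
        "nest_lon": None if sc.non_breeder else sc.nest_lon,
        "nest_lat": None if sc.non_breeder else sc.nest_lat,
        "fate": None if sc.non_breeder else sc.fate,
        "failure_day": None if sc.non_breeder else sc.failure_day,
        "start_date": sc.start_date,
        "t_full": sc.t_full,
        "non_breeder": sc.non_breeder,
    }
    return track, truth


# ---------------------------------------------------------------------------
# direct draws from the survival/detection model

def simulate_histories(
    params: ModelParams,
    T: int,
    n_attempts: int,
    fixes_per_day,
    seed: int = 0,
) -> tuple[list[VisitHistory], np.ndarray]:
    """Exact generative draws of (z, Y) from the model equations.

    ``fixes_per_day`` is an int or a length-T vector for N_t. Returns the
    histories and the true latent paths z (n_attempts, T).
    """
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(1, T + 1, dtype=float)
    phi = params.phi(t)
    p = params.p(t)
    N = np.broadcast_to(np.asarray(fixes_per_day, dtype=np.int64), (T,)) if np.ndim(fixes_per_day) else np.full(T, int(fixes_per_day), dtype=np.int64)
    z = np.zeros((n_attempts, T), dtype=np.int64)
    Y = np.zeros((n_attempts, T), dtype=np.int64)
    z[:, 0] = 1
    Y[:, 0] = rng.binomial(N[0], p[0], size=n_attempts)
    for j in range(1, T):
        z[:, j] = rng.binomial(1, z[:, j - 1] * phi[j - 1])
        Y[:, j] = rng.binomial(N[j], z[:, j] * p[j])
    histories = [
        VisitHistory(attempt_id=f"sim{i:03d}", T=T, N=N.copy(), Y=Y[i]) for i in range(n_attempts)
    ]
    return histories, z


def simulate_fate_cohort(
    n_success: int,
    n_failure: int,
    T: int,
    fixes_per_day: int = 10,
    attendance: float = 0.9,
    failure_day_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[list[VisitHistory], list[str]]:
    """Planted-fate cohort: successes visit through day T, failures stop.

    Failure days are uniform in ``failure_day_range`` (default [5, T-5]).
    Returns the histories and the true fate labels.
    """
    rng = np.random.default_rng(seed)
    lo, hi = failure_day_range or (5, T - 5)
    histories = []
    fates = []
    for i in range(n_success + n_failure):
        success = i < n_success
        f_day = T if success else int(rng.integers(lo, hi + 1))
        N = np.full(T, fixes_per_day, dtype=np.int64)
        z = (np.arange(1, T + 1) <= f_day).astype(np.int64)
        Y = rng.binomial(N, z * attendance)
        if Y[0] == 0:  # day 1 anchors at the first nest visit by construction
            Y[0] = 1
        histories.append(VisitHistory(attempt_id=f"cohort{i:03d}", T=T, N=N, Y=Y))
        fates.append("success" if success else "failure")
    return histories, fates


def simulate_labeled_metrics(
    n: int,
    rule: dict | None = None,
    label_noise: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-space draws for CART threshold-recovery experiments.

    Metrics are drawn uniformly over their natural ranges and labeled
    "nest" by a planted conjunction of minimum thresholds (default:
    consec_days >= 12 and perc_top_vis >= 60), then a fraction of labels
    is flipped.
    """
    rule = rule or {"consec_days": 12, "perc_top_vis": 60.0}
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "consec_days": rng.integers(1, 41, n),
            "perc_days_vis": rng.uniform(10.0, 100.0, n),
            "perc_top_vis": rng.uniform(0.0, 100.0, n),
        }
    )
    is_nest = np.ones(n, dtype=bool)
    for feat, thr in rule.items():
        is_nest &= df[feat].to_numpy() >= thr
    flip = rng.random(n) < label_noise
    df["label"] = np.where(is_nest ^ flip, "nest", "non-nest")
    return df
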
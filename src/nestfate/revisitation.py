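"""Recurrently visited locations and their revisitation metrics.

Every fix of a track is a potential site center: a circular buffer of
radius r around it collects the fixes that fall inside, and a location is
"revisited" when that buffer holds fixes from at least two distinct
calendar days (returning, not merely lingering within one day). For each
revisited location three diagnostic metrics summarise the temporal pattern
of visits:

* ``consec_days`` — the longest run of consecutive days with at least one
  in-buffer fix;
* ``perc_days_vis`` — the percentage of days visited between the first and
  last visit (inclusive span);
* ``perc_top_vis`` — on the day of maximum attendance ("top day"), the
  percentage of that day's fixes that are inside the buffer.

Nests sit at the high end of all three; foraging patches, roosts and
perches usually do not, which is what the downstream filtering exploits.

A uniform lon/lat grid accelerates the buffer scan; correctness is defined
solely by the brute-force pairwise-distance contract and the grid falls
back to brute force whenever the geometry makes cell bounds unsafe (near
poles, dateline-crossing tracks, projected coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .geo_tracks import Track, haversine_m

__all__ = [
    "BufferSpec",
    "RevisitationMetrics",
    "CandidateSite",
    "fixes_in_buffer",
    "compute_metrics",
    "find_revisited_locations",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class BufferSpec:
    """Radius (metres) of the circular buffer placed on each fix."""

    radius_r: float

    def __post_init__(self) -> None:
        if not self.radius_r > 0:
            raise ValueError("radius_r must be > 0")


@dataclass(frozen=True)
class RevisitationMetrics:
    consec_days: int
    perc_days_vis: float
    perc_top_vis: float
    n_fixes_in: int
    first_day: date
    last_day: date


@dataclass(frozen=True)
class CandidateSite:
    """A revisited location: buffer center, members and metrics."""

    track_id: str
    center_index: int
    center_lon: float
    center_lat: float
    metrics: RevisitationMetrics
    member_fix_indices: np.ndarray

    @property
    def n_fixes_in(self) -> int:
        return self.metrics.n_fixes_in

    @property
    def first_day(self) -> date:
        return self.metrics.first_day

    @property
    def last_day(self) -> date:
        return self.metrics.last_day


# ---------------------------------------------------------------------------
# buffer scan

def _members_brute(track: Track, center_index: int, radius: float) -> np.ndarray:
    d = track.distances_to(track.lon[center_index], track.lat[center_index])
    return np.flatnonzero(d <= radius)


def fixes_in_buffer(track: Track, center_index: int, buffer: BufferSpec) -> np.ndarray:
    """Indices of all fixes within ``radius_r`` of the center fix (inclusive)."""
    if not (0 <= center_index < track.n_fixes):
        raise IndexError(f"center_index {center_index} out of range")
    return _members_brute(track, center_index, buffer.radius_r)


def _grid_safe(track: Track) -> bool:
    if track.crs != "lonlat" or track.n_fixes == 0:
        return False
    if np.max(np.abs(track.lat)) > 85.0:
        return False
    if np.max(track.lon) - np.min(track.lon) > 180.0:  # possible dateline wrap
        return False
    return True


def _all_buffer_members(track: Track, radius: float) -> list[np.ndarray]:
    """Member index set for every fix as center.

    Grid cells are sized conservatively (>= r in haversine metres in both
    dimensions over the track's latitude range) so a 3x3 neighbourhood is
    guaranteed to contain every point within r of a center; the final test
    is always the exact distance.
    """
    n = track.n_fixes
    if n <= 200 or not _grid_safe(track):
        return [_members_brute(track, i, radius) for i in range(n)]

    lat = track.lat
    lon = track.lon
    cos_min = np.cos(np.radians(np.max(np.abs(lat))))
    cell_lat = radius / 110_500.0  # deg; metres-per-degree-lat lower bound
    cell_lon = radius / (110_500.0 * max(cos_min, 1e-6))
    ix = np.floor(lon / cell_lon).astype(np.int64)
    iy = np.floor(lat / cell_lat).astype(np.int64)
    buckets: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        buckets.setdefault((ix[i], iy[i]), []).append(i)
    members: list[np.ndarray] = []
    for i in range(n):
        cand: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                cand.extend(buckets.get((ix[i] + dx, iy[i] + dy), ()))
        cand_arr = np.asarray(sorted(cand), dtype=np.int64)
        d = haversine_m(lon[cand_arr], lat[cand_arr], lon[i], lat[i])
        members.append(cand_arr[d <= radius])
    return members


# ---------------------------------------------------------------------------
# metrics

def _longest_run(sorted_vals: np.ndarray) -> int:
    if len(sorted_vals) == 0:
        return 0
    breaks = np.flatnonzero(np.diff(sorted_vals) != 1)
    runs = np.diff(np.concatenate(([-1], breaks, [len(sorted_vals) - 1])))
    return int(runs.max())


def compute_metrics(
    track: Track,
    member_indices,
    tz: str = "UTC",
    skip_missing_days: bool = False,
    day_ords: np.ndarray | None = None,
) -> RevisitationMetrics:
    """Revisitation metrics for one buffer's member fixes.

    With ``skip_missing_days`` (accounting for tag silence / fix failure),
    days on which the track recorded no fixes at all are ignored: they
    neither break consecutive-day runs nor count in the ``perc_days_vis``
    denominator. By default they do both.
    """
    members = np.asarray(member_indices, dtype=np.int64)
    if members.size == 0:
        raise ValueError("member set must be non-empty")
    if day_ords is None:
        day_ords = track.day_ordinals(tz)
    mdays = np.unique(day_ords[members])
    first_o, last_o = int(mdays[0]), int(mdays[-1])

    if skip_missing_days:
        track_days = np.unique(day_ords)
        in_span = track_days[(track_days >= first_o) & (track_days <= last_o)]
        # positions of member days in the observed-day sequence
        pos = np.searchsorted(in_span, mdays)
        consec = _longest_run(pos)
        denom = len(in_span)
    else:
        consec = _longest_run(mdays)
        denom = last_o - first_o + 1
    perc_days = 100.0 * len(mdays) / denom

    # attendance per member day: member fixes / all track fixes that day
    day_totals = pd.Series(day_ords).value_counts()
    mem_counts = pd.Series(day_ords[members]).value_counts()
    top = 100.0 * float((mem_counts / day_totals.loc[mem_counts.index]).max())

    return RevisitationMetrics(
        consec_days=consec,
        perc_days_vis=perc_days,
        perc_top_vis=top,
        n_fixes_in=int(members.size),
        first_day=date.fromordinal(first_o + date(1970, 1, 1).toordinal()),
        last_day=date.fromordinal(last_o + date(1970, 1, 1).toordinal()),
    )


# ---------------------------------------------------------------------------
# candidate scan

def find_revisited_locations(
    track: Track,
    buffer: BufferSpec,
    min_thresholds=None,
    tz: str = "UTC",
    skip_missing_days: bool = False,
) -> list[CandidateSite]:
    """Scan a track for revisited locations (candidate nest sites).

    Every fix is a candidate center. Candidates must contain fixes from at
    least two distinct calendar days; candidates with identical member sets
    are deduplicated to the lowest-index representative. ``min_thresholds``
    (any object with ``min_consec_days`` / ``min_days_vis_pct`` /
    ``min_top_vis_pct``, all-zero = no filtering) prunes by metrics.
    Result sorted by ``n_fixes_in`` descending.
    """
    if track.n_fixes == 0:
        raise ValueError("track has no fixes")
    day_ords = track.day_ordinals(tz)
    members_all = _all_buffer_members(track, buffer.radius_r)

    seen: set[bytes] = set()
    out: list[CandidateSite] = []
    for i, members in enumerate(members_all):
        if members.size < 2:
            continue
        if len(np.unique(day_ords[members])) < 2:
            continue
        key = members.tobytes()
        if key in seen:
            continue
        seen.add(key)
        m = compute_metrics(track, members, tz=tz, skip_missing_days=skip_missing_days, day_ords=day_ords)
        if min_thresholds is not None:
            if (
                m.consec_days < getattr(min_thresholds, "min_consec_days", 0)
                or m.perc_days_vis < getattr(min_thresholds, "min_days_vis_pct", 0)
                or m.perc_top_vis < getattr(min_thresholds, "min_top_vis_pct", 0)
            ):
                continue
        out.append(
            CandidateSite(
                track_id=track.id,
                center_index=i,
                center_lon=float(track.lon[i]),
                center_lat=float(track.lat[i]),
                metrics=m,
                member_fix_indices=members,
            )
        )
    out.sort(
        key=lambda c: (-c.n_fixes_in, c.first_day, c.center_lon, c.center_lat, c.center_index)
    )
    return out


def candidates_to_frame(candidates) -> pd.DataFrame:
    """Candidate table in the CSV export layout."""
    rows = [
        {
            "id": c.track_id,
            "center_lon": c.center_lon,
            "center_lat": c.center_lat,
            "first_day": c.first_day,
            "last_day": c.last_day,
            "n_fixes_in": c.n_fixes_in,
            "consec_days": c.metrics.consec_days,
            "perc_days_vis": c.metrics.perc_days_vis,
            "perc_top_vis": c.metrics.perc_top_vis,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id", "center_lon", "center_lat", "first_day", "last_day",
            "n_fixes_in", "consec_days", "perc_days_vis", "perc_top_vis",
        ],
    )
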
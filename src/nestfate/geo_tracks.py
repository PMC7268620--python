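"""Reading, validating and windowing GPS trajectories.

A trajectory ("track") is the unit of analysis: the time-ordered GPS fixes
of one individual in one year. Everything downstream — revisitation scans,
nest filtering, visit histories — consumes tracks through this module, which
also owns the two conventions the rest of the package relies on:

* distances are great-circle metres on a sphere of radius 6 371 000 m
  (an ``xy`` mode accepts pre-projected metric coordinates and uses
  Euclidean distance instead);
* a "day" is the calendar date of a fix in a configurable timezone
  (default UTC), exposed as an integer ordinal so day arithmetic is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("nestfate")

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "Fix",
    "Track",
    "SeasonWindow",
    "distance_m",
    "haversine_m",
    "read_tracks",
    "write_tracks",
    "restrict_to_season",
]


@dataclass(frozen=True)
class Fix:
    """A single GPS location record."""

    timestamp: pd.Timestamp
    lon: float
    lat: float

    def __post_init__(self) -> None:
        ts = pd.Timestamp(self.timestamp)
        if ts.tzinfo is None:
            raise ValueError("Fix timestamp must be timezone-aware")
        if pd.isna(ts):
            raise ValueError("Fix timestamp must be finite")
        object.__setattr__(self, "timestamp", ts)
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")


def haversine_m(lon1, lat1, lon2, lat2):
    """Vectorized great-circle distance in metres (spherical Earth)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_m(a: Fix, b: Fix) -> float:
    """Great-circle distance between two fixes in metres."""
    return float(haversine_m(a.lon, a.lat, b.lon, b.lat))


@dataclass
class Track:
    """Time-ordered GPS fixes for one individual-year.

    Coordinates are stored as arrays; ``crs="lonlat"`` (default) means
    decimal degrees with haversine distances, ``crs="xy"`` means projected
    metric coordinates with Euclidean distances.
    """

    id: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    nominal_interval: float = 60.0  # minutes
    crs: str = "lonlat"

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        if self.times.tz is None:
            raise ValueError(f"track {self.id}: timestamps must be timezone-aware")
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.times) == len(self.lon) == len(self.lat)):
            raise ValueError(f"track {self.id}: coordinate/time length mismatch")
        if self.nominal_interval <= 0:
            raise ValueError("nominal_interval must be > 0")
        if self.crs not in ("lonlat", "xy"):
            raise ValueError(f"unknown crs {self.crs!r}")
        if len(self.times) > 1:
            deltas = np.diff(self.times.asi8)
            if np.any(deltas == 0):
                raise ValueError(f"track {self.id}: duplicate timestamps")
            if np.any(deltas < 0):
                order = np.argsort(self.times.asi8, kind="stable")
                self.times = self.times[order]
                self.lon = self.lon[order]
                self.lat = self.lat[order]
        if self.crs == "lonlat" and len(self.lon):
            if np.any(np.abs(self.lon) > 180) or np.any(np.abs(self.lat) > 90):
                raise ValueError(f"track {self.id}: coordinates out of range")

    @property
    def n_fixes(self) -> int:
        return len(self.times)

    @property
    def fixes(self) -> list[Fix]:
        return [Fix(t, lo, la) for t, lo, la in zip(self.times, self.lon, self.lat)]

    def day_ordinals(self, tz: str = "UTC") -> np.ndarray:
        """Calendar day of each fix as a proleptic-Gregorian ordinal."""
        if len(self.times) == 0:
            return np.empty(0, dtype=np.int64)
        local = self.times.tz_convert(tz)
        # floor to day, then express as days since epoch
        return np.asarray(local.normalize().tz_localize(None).asi8 // 86_400_000_000_000, dtype=np.int64)

    def distances_to(self, lon: float, lat: float) -> np.ndarray:
        """Distance in metres from every fix to a reference point."""
        if self.crs == "xy":
            return np.hypot(self.lon - lon, self.lat - lat)
        return haversine_m(self.lon, self.lat, lon, lat)

    def subset(self, mask_or_idx) -> "Track":
        return replace(
            self,
            times=self.times[mask_or_idx],
            lon=self.lon[mask_or_idx],
            lat=self.lat[mask_or_idx],
        )


@dataclass(frozen=True)
class SeasonWindow:
    """Annual month-day window; may wrap the year boundary (e.g. Nov-Aug)."""

    start: tuple[int, int]  # (month, day)
    end: tuple[int, int]

    def __post_init__(self) -> None:
        for m, d in (self.start, self.end):
            if not (1 <= m <= 12 and 1 <= d <= 31):
                raise ValueError(f"invalid month-day {(m, d)}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def contains(self, month: int, day: int) -> bool:
        md = (month, day)
        if self.wraps:
            return md >= self.start or md <= self.end
        return self.start <= md <= self.end


def _parse_timestamps(raw: pd.Series, path) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, utc=True, errors="coerce", format="mixed")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: unparseable timestamp {raw.iloc[row]!r} at data row {raw.index[row]}")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(f"{path}: missing timestamp at data row {parsed.index[row]}")
    return pd.DatetimeIndex(parsed)


DEFAULT_COLUMNS = {"id": "id", "timestamp": "timestamp", "lon": "lon", "lat": "lat"}


def read_tracks(
    path,
    column_map: Mapping[str, str] | None = None,
    nominal_interval: float = 60.0,
    sep: str | None = None,
    crs: str = "lonlat",
) -> list[Track]:
    """Read a tabular fix file into one :class:`Track` per unique id.

    Rows are sorted by time within id; rows with missing coordinates are
    dropped (counted in the log). Unparseable timestamps are a hard error.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    n_before = len(df)
    df = df.dropna(subset=["lon", "lat"])
    dropped = n_before - len(df)
    if dropped:
        logger.info("read_tracks: dropped %d rows with missing coordinates from %s", dropped, path)
    if df.empty:
        raise ValueError(f"{path}: all rows have missing coordinates")
    times = _parse_timestamps(df["timestamp"], path)
    df = df.assign(_ts=times)
    tracks: list[Track] = []
    for tid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("_ts", kind="stable")
        tracks.append(
            Track(
                id=str(tid),
                times=pd.DatetimeIndex(grp["_ts"]),
                lon=grp["lon"].to_numpy(dtype=float),
                lat=grp["lat"].to_numpy(dtype=float),
                nominal_interval=nominal_interval,
                crs=crs,
            )
        )
    return tracks


def write_tracks(tracks: Iterable[Track], path, column_map: Mapping[str, str] | None = None) -> None:
    """Write tracks back to CSV in the dialect :func:`read_tracks` reads."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    cols["id"]: tr.id,
                    cols["timestamp"]: tr.times.strftime("%Y-%m-%dT%H:%M:%S%z"),
                    cols["lon"]: tr.lon,
                    cols["lat"]: tr.lat,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def restrict_to_season(track: Track, window: SeasonWindow, tz: str = "UTC") -> Track:
    """Keep only fixes whose local month-day falls inside the window (inclusive)."""
    if track.n_fixes == 0:
        return track
    local = track.times.tz_convert(tz)
    months = np.asarray(local.month)
    days = np.asarray(local.day)
    keep = np.fromiter(
        (window.contains(m, d) for m, d in zip(months, days)), dtype=bool, count=len(months)
    )
    return track.subset(keep)
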
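"""GPS track containers, readers, and preprocessing filters.

The raw material of every downstream step is a :class:`Track`: one cat's
time-ordered GPS fixes with the per-fix quality fields the receiver reports
(elevation, EHPE).  Preprocessing follows four removal rules — elevation
range, first days of deployment, data-download days, and an EHPE cutoff —
followed by greedy temporal thinning to a minimum fix interval.  Daily
outdoor tracking coverage and the per-cat aggregation weight (mean fraction
of a 24-h day tracked outdoors) are computed here as well.

Coordinates are planar meters in a projected CRS; timestamps are UTC.
Calendar-day boundaries (used by the first-days, download-day and daily
coverage computations) are taken in a configurable local time zone,
expressed as a fixed UTC offset in hours (default +2, Central European
Summer Time).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Columns a fix table must carry, in canonical order.
FIX_COLUMNS = ["cat_id", "timestamp", "x", "y", "elevation", "ehpe"]

#: Default local-time offset from UTC, hours, for calendar-day boundaries.
DEFAULT_TZ_OFFSET_HOURS = 2.0


class TrackFormatError(ValueError):
    """Raised when an input fix table violates the expected CSV dialect."""


@dataclass(frozen=True)
class GpsFix:
    """A single GPS position fix."""

    cat_id: str
    timestamp: dt.datetime
    x: float
    y: float
    elevation: float
    ehpe: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.x) or not np.isfinite(self.y):
            raise ValueError("fix coordinates must be finite")
        if self.ehpe < 0:
            raise ValueError("ehpe must be nonnegative")


@dataclass
class Track:
    """Time-ordered GPS fixes for one cat.

    Parameters
    ----------
    cat_id : str
        Animal identifier; all fixes share it.
    fixes : pandas.DataFrame
        Columns ``timestamp`` (datetime64, UTC, strictly increasing),
        ``x``, ``y`` (projected meters), ``elevation`` (m), ``ehpe``.
    deployment_start : datetime.date, optional
        First day of tracking (local calendar date).  Defaults to the local
        date of the first fix.
    download_dates : set of datetime.date
        Local calendar dates on which the unit was retrieved for download.
    crs_tag : str
        Identifier of the projected CRS the coordinates live in.
    tz_offset_hours : float
        Fixed UTC offset used to derive local calendar dates.
    """

    cat_id: str
    fixes: pd.DataFrame
    deployment_start: dt.date | None = None
    download_dates: set[dt.date] = field(default_factory=set)
    crs_tag: str = "local-meters"
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS

    def __post_init__(self) -> None:
        f = self.fixes.reset_index(drop=True)
        missing = [c for c in ("timestamp", "x", "y", "elevation", "ehpe") if c not in f.columns]
        if missing:
            raise TrackFormatError(f"fix table missing column(s): {', '.join(missing)}")
        t = pd.to_datetime(f["timestamp"])
        if t.is_monotonic_increasing and t.is_unique:
            f = f.assign(timestamp=t)
        else:
            f = f.assign(timestamp=t).sort_values("timestamp", kind="mergesort")
            f = f.drop_duplicates(subset="timestamp", keep="first").reset_index(drop=True)
        self.fixes = f.reset_index(drop=True)
        if self.deployment_start is None and len(self.fixes):
            self.deployment_start = self.local_dates()[0]

    # -- basic accessors ---------------------------------------------------

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def times_s(self) -> np.ndarray:
        """Fix times as float seconds since the first fix's epoch."""
        t = self.fixes["timestamp"].to_numpy(dtype="datetime64[ns]")
        return (t - t[0]).astype("timedelta64[ns]").astype(np.int64) / 1e9 if len(t) else np.array([])

    def epoch_s(self) -> np.ndarray:
        """Fix times as float seconds since the Unix epoch."""
        t = self.fixes["timestamp"].to_numpy(dtype="datetime64[ns]")
        return t.astype("datetime64[s]").astype(np.int64).astype(float)

    def xy(self) -> np.ndarray:
        """(n, 2) array of projected coordinates."""
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    def local_dates(self) -> np.ndarray:
        """Local calendar date of each fix (object array of datetime.date)."""
        shifted = self.fixes["timestamp"] + pd.to_timedelta(self.tz_offset_hours, unit="h")
        return shifted.dt.date.to_numpy()

    def _replace_fixes(self, mask: np.ndarray) -> "Track":
        return dataclasses.replace(self, fixes=self.fixes.loc[mask].reset_index(drop=True))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.fixes)


@dataclass
class StudyCat:
    """Per-cat metadata: demography and the owner's residence footprint."""

    cat_id: str
    home_polygon: "object"  # shapely Polygon
    sex: str = "unknown"  # {"F", "M", "unknown"}
    age_years: float | None = None
    sterilized: bool | None = None

    def __post_init__(self) -> None:
        poly = self.home_polygon
        if poly is None or not poly.is_valid or poly.area <= 0:
            raise ValueError(f"home polygon for {self.cat_id} must be valid with positive area")

    @property
    def home_point(self) -> tuple[float, float]:
        c = self.home_polygon.centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class DailyCoverage:
    """Hours of outdoor tracking on one local calendar day."""

    cat_id: str
    date: dt.date
    outdoor_hours: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.outdoor_hours <= 24.0:
            raise ValueError("outdoor_hours must lie in [0, 24]")


@dataclass(frozen=True)
class OutdoorWeight:
    """Mean fraction of a 24-h day tracked outdoors, over days with data.

    This is the aggregation weight w applied to the cat's utilization
    distribution when building the population-level surface.
    """

    cat_id: str
    w: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("outdoor weight must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_fix_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: one for the header row, one for 1-based line numbering
        line = int(bad[0]) + 2
        raise TrackFormatError(
            f"{path}: unparseable timestamp {df['timestamp'].iloc[bad[0]]!r} at line {line}"
        )
    out = df.copy()
    out["timestamp"] = ts.dt.tz_localize(None)  # naive UTC internally
    for col in ("x", "y", "elevation", "ehpe"):
        out[col] = pd.to_numeric(out[col], errors="raise")
    return out


def read_tracks(
    path,
    crs_tag: str = "local-meters",
    download_dates: Mapping[str, Iterable[dt.date]] | None = None,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
) -> dict[str, Track]:
    """Read a fix CSV and partition it into per-cat :class:`Track` objects.

    The CSV must carry the header ``cat_id,timestamp,x,y,elevation,ehpe``
    with ISO-8601 timestamps.  Rows are sorted by time per cat; exact
    duplicate ``(cat_id, timestamp)`` rows collapse to the first occurrence.
    """
    df = pd.read_csv(path, dtype={"cat_id": str})
    df = _parse_fix_frame(df, path)
    tracks: dict[str, Track] = {}
    for cat_id, grp in df.groupby("cat_id", sort=True):
        dl = set(download_dates.get(cat_id, ())) if download_dates else set()
        tracks[cat_id] = Track(
            cat_id=str(cat_id),
            fixes=grp[["timestamp", "x", "y", "elevation", "ehpe"]],
            download_dates=dl,
            crs_tag=crs_tag,
            tz_offset_hours=tz_offset_hours,
        )
    return tracks


_EARTH_RADIUS_M = 6_371_008.8


def lonlat_to_local_xy(
    lon: np.ndarray, lat: np.ndarray, lon0: float | None = None, lat0: float | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Project WGS84 lon/lat to local planar meters.

    Uses a local azimuthal-equidistant approximation about the data centroid
    (adequate at neighbourhood scale, sub-meter over a few km).  Returns
    x (east), y (north) and the (lon0, lat0) origin used.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    x = np.radians(lon - lon0) * _EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS_M
    return x, y, (lon0, lat0)


def read_tracks_lonlat(
    path,
    crs_tag: str = "local-aeqd",
    download_dates: Mapping[str, Iterable[dt.date]] | None = None,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
) -> dict[str, Track]:
    """Read a GPX-style CSV with ``lon``/``lat`` columns and project to meters.

    Same dialect as :func:`read_tracks` but with ``lon,lat`` (WGS84 degrees)
    in place of ``x,y``; one shared local origin is used for all cats so the
    resulting tracks live in a common planar frame.
    """
    df = pd.read_csv(path, dtype={"cat_id": str})
    needed = ["cat_id", "timestamp", "lon", "lat", "elevation", "ehpe"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    x, y, _origin = lonlat_to_local_xy(df["lon"].to_numpy(), df["lat"].to_numpy())
    df = df.assign(x=x, y=y)[FIX_COLUMNS]
    df = _parse_fix_frame(df, path)
    tracks: dict[str, Track] = {}
    for cat_id, grp in df.groupby("cat_id", sort=True):
        dl = set(download_dates.get(cat_id, ())) if download_dates else set()
        tracks[cat_id] = Track(
            cat_id=str(cat_id),
            fixes=grp[["timestamp", "x", "y", "elevation", "ehpe"]],
            download_dates=dl,
            crs_tag=crs_tag,
            tz_offset_hours=tz_offset_hours,
        )
    return tracks


def write_tracks(tracks: Iterable[Track] | Mapping[str, Track], path) -> None:
    """Write tracks back to the canonical CSV dialect (deterministic bytes)."""
    if isinstance(tracks, Mapping):
        tracks = [tracks[k] for k in sorted(tracks)]
    frames = []
    for tr in tracks:
        f = tr.fixes.copy()
        f.insert(0, "cat_id", tr.cat_id)
        frames.append(f)
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=FIX_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# The four removal rules + thinning
# ---------------------------------------------------------------------------


def filter_elevation(track: Track, min_elev: float = 0.0, max_elev: float = 300.0) -> Track:
    """Remove fixes whose elevation falls outside the closed [min, max] range."""
    e = track.fixes["elevation"].to_numpy(dtype=float)
    return track._replace_fixes((e >= min_elev) & (e <= max_elev))


def filter_first_days(track: Track, n_days: int = 2) -> Track:
    """Remove fixes from the first ``n_days`` calendar days of deployment."""
    if track.n_fixes == 0:
        return track
    start = track.deployment_start
    cutoff = start + dt.timedelta(days=n_days)
    dates = track.local_dates()
    return track._replace_fixes(np.array([d >= cutoff for d in dates]))


def filter_download_days(track: Track) -> Track:
    """Remove fixes from days on which the GPS unit was retrieved for download."""
    if not track.download_dates or track.n_fixes == 0:
        return track
    dates = track.local_dates()
    return track._replace_fixes(np.array([d not in track.download_dates for d in dates]))


def filter_ehpe(track: Track, max_ehpe: float = 5000.0) -> Track:
    """Remove fixes whose estimated horizontal position error is >= ``max_ehpe``.

    EHPE is passed through in raw device units; the default cutoff removes
    fixes at or above 5000.
    """
    e = track.fixes["ehpe"].to_numpy(dtype=float)
    return track._replace_fixes(e < max_ehpe)


def thin_track(track: Track, min_interval: float = 120.0) -> Track:
    """Greedily thin fixes to a minimum inter-fix interval (seconds).

    Keeps the first fix, then each later fix only if it lies at least
    ``min_interval`` after the last kept one; all retained intervals are
    therefore >= ``min_interval``.  Idempotent.
    """
    if track.n_fixes <= 1:
        return track
    t = track.times_s()
    keep = np.zeros(len(t), dtype=bool)
    keep[0] = True
    last = t[0]
    for i in range(1, len(t)):
        if t[i] >= last + min_interval:
            keep[i] = True
            last = t[i]
    return track._replace_fixes(keep)


def apply_standard_filters(
    track: Track,
    min_elev: float = 0.0,
    max_elev: float = 300.0,
    first_days: int = 2,
    max_ehpe: float = 5000.0,
) -> Track:
    """The four removal rules in the standard order (no thinning)."""
    track = filter_elevation(track, min_elev, max_elev)
    track = filter_first_days(track, first_days)
    track = filter_download_days(track)
    track = filter_ehpe(track, max_ehpe)
    return track


# ---------------------------------------------------------------------------
# Coverage and aggregation weight
# ---------------------------------------------------------------------------


def daily_coverage(track: Track, gap_cap: float = 1800.0) -> list[DailyCoverage]:
    """Outdoor tracking hours per local calendar day.

    Coverage for a day is the sum, over consecutive same-day fix pairs, of
    the inter-fix interval capped at ``gap_cap`` seconds (default 30 min).
    The cap prevents a lone pair of fixes hours apart from claiming the gap
    as continuous coverage.  Days with a single fix contribute 0 h but still
    count as days with data.

    The track should already be filtered to outdoor fixes.
    """
    out: list[DailyCoverage] = []
    if track.n_fixes == 0:
        return out
    dates = track.local_dates()
    t = track.times_s()
    for day in sorted(set(dates)):
        idx = np.flatnonzero(dates == day)
        td = t[idx]
        hours = float(np.minimum(np.diff(td), gap_cap).sum() / 3600.0) if len(td) > 1 else 0.0
        out.append(DailyCoverage(track.cat_id, day, min(hours, 24.0)))
    return out


def outdoor_weight(coverages: Sequence[DailyCoverage]) -> OutdoorWeight:
    """Aggregation weight w: mean of outdoor_hours/24 over days with data."""
    if not coverages:
        raise ValueError("cannot compute outdoor weight: no days with data")
    cat_ids = {c.cat_id for c in coverages}
    if len(cat_ids) != 1:
        raise ValueError("coverages must belong to a single cat")
    w = float(np.mean([c.outdoor_hours / 24.0 for c in coverages]))
    return OutdoorWeight(cat_ids.pop(), w)
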
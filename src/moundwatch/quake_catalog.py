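"""Earthquake catalogs: parsing, distance filtering and event-locked windows.

The monitored mounds sit on tectonically active, gas-permeable faults in a
region producing on the order of a hundred small earthquakes per year.
Behavioral correlation needs (a) the catalog of local events filtered by
epicentral distance and magnitude relative to a camera location, and
(b) activity-index segments re-timed relative to each event's origin so
that pre-event anomalies (suppression of the nocturnal rest phase) can be
screened against a reference daily profile.

Three transcribed reference catalogs ship with the package (M > 2.0
events 2009-2012 within 40 km of the cameras; all September 2009 events;
all June 2010 events) and can be loaded with :func:`load_builtin_catalog`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from importlib import resources
from math import asin, atan2, cos, degrees, radians, sin, sqrt
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class QuakeEvent:
    label: str
    origin_time: datetime
    depth_km: float
    magnitude: float
    lon_deg: float
    lat_deg: float
    depth_manual: bool = False  # depth determined manually (asterisked rows)

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon_deg <= 180.0 or not -90.0 <= self.lat_deg <= 90.0:
            raise CatalogError(f"coordinates out of range for {self.label!r}")
        if not np.isfinite(self.magnitude):
            raise CatalogError(f"non-finite magnitude for {self.label!r}")


@dataclass(frozen=True)
class StationLocation:
    """A camera site. Coordinates are configuration, never built in."""

    label: str
    lon_deg: float
    lat_deg: float


def read_catalog(path: str | Path) -> list[QuakeEvent]:
    """Parse a catalog CSV into time-sorted events.

    Expected columns: label, date, time_utc, depth_km, magnitude, lon, lat
    and optionally depth_manual (0/1). Malformed rows raise with their row
    number so transcription errors surface immediately.
    """
    df = pd.read_csv(path)
    events = []
    for i, row in df.iterrows():
        try:
            origin = pd.Timestamp(f"{row['date']} {row['time_utc']}", tz="UTC")
            events.append(
                QuakeEvent(
                    label=str(row["label"]),
                    origin_time=origin.to_pydatetime(),
                    depth_km=float(row["depth_km"]),
                    magnitude=float(row["magnitude"]),
                    lon_deg=float(row["lon"]),
                    lat_deg=float(row["lat"]),
                    depth_manual=bool(row.get("depth_manual", 0)),
                )
            )
        except (KeyError, ValueError, CatalogError) as exc:
            raise CatalogError(f"malformed catalog row {i}: {exc}") from exc
    return sorted(events, key=lambda e: e.origin_time)


def load_builtin_catalog(name: str) -> list[QuakeEvent]:
    """Load a shipped reference catalog: "table1", "table2" or "table3"."""
    ref = resources.files("moundwatch.data") / f"{name}.csv"
    with resources.as_file(ref) as path:
        return read_catalog(path)


def haversine_km(
    a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Great-circle distance in km between (lon_deg, lat_deg) points."""
    lon1, lat1 = map(radians, a)
    lon2, lat2 = map(radians, b)
    h = sin((lat2 - lat1) / 2) ** 2 + cos(lat1) * cos(lat2) * sin(
        (lon2 - lon1) / 2
    ) ** 2
    return 2.0 * EARTH_RADIUS_KM * asin(min(1.0, sqrt(h)))


def destination_point(
    origin: tuple[float, float], bearing_deg: float, distance_km: float
) -> tuple[float, float]:
    """Point at a given initial bearing and great-circle distance from origin.

    Inverse of the haversine distance along a geodesic; used by the
    synthetic catalog generator to place epicenters uniformly in a disc.
    """
    lon1, lat1 = map(radians, origin)
    brg = radians(bearing_deg)
    d = distance_km / EARTH_RADIUS_KM
    lat2 = asin(sin(lat1) * cos(d) + cos(lat1) * sin(d) * cos(brg))
    lon2 = lon1 + atan2(
        sin(brg) * sin(d) * cos(lat1), cos(d) - sin(lat1) * sin(lat2)
    )
    return (degrees(lon2), degrees(lat2))


def filter_events(
    catalog: list[QuakeEvent],
    station: StationLocation,
    radius_km: float,
    min_magnitude: float,
) -> list[QuakeEvent]:
    """Events within ``radius_km`` of the station with magnitude strictly
    greater than ``min_magnitude``, time-sorted."""
    kept = [
        e
        for e in catalog
        if e.magnitude > min_magnitude
        and haversine_km((station.lon_deg, station.lat_deg), (e.lon_deg, e.lat_deg))
        <= radius_km
    ]
    return sorted(kept, key=lambda e: e.origin_time)


@dataclass
class EventWindow:
    """Activity segment re-timed relative to an event origin (t = 0)."""

    event: QuakeEvent
    t_rel_hours: np.ndarray
    values: np.ndarray
    coverage: float  # fraction of the requested window covered by samples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_rel_hours": self.t_rel_hours, "index": self.values}
        )


def extract_event_window(
    series: pd.Series,
    event: QuakeEvent,
    pre_hours: float = 24.0,
    post_hours: float = 24.0,
) -> EventWindow:
    """Slice an index series to [origin - pre, origin + post].

    ``series`` is UTC-datetime indexed (the calibrated, filtered activity
    index). Coverage is the spanned fraction of the requested window; zero
    overlap is an error because the event cannot be assessed at all.
    """
    origin = event.origin_time
    if origin.tzinfo is None:
        origin = origin.replace(tzinfo=timezone.utc)
    start = origin - timedelta(hours=pre_hours)
    end = origin + timedelta(hours=post_hours)
    segment = series[(series.index >= start) & (series.index <= end)]
    if len(segment) == 0:
        raise CatalogError(f"event outside series: {event.label}")
    t_rel = (segment.index - origin).total_seconds() / 3600.0
    spanned = (segment.index[-1] - segment.index[0]).total_seconds() / 3600.0
    coverage = min(1.0, spanned / (pre_hours + post_hours))
    return EventWindow(
        event=event,
        t_rel_hours=np.asarray(t_rel, dtype=float),
        values=segment.to_numpy(dtype=float),
        coverage=float(coverage),
    )


def flag_rest_suppression(
    night_values: np.ndarray,
    baseline_night_means: np.ndarray,
    threshold: float = 3.0,
    min_baseline_nights: int = 5,
) -> tuple[bool, float]:
    """Screen one night's activity against a reference of normal nights.

    ``baseline_night_means`` holds the mean nocturnal index of each
    reference night (>= ``min_baseline_nights`` of them). The score is the
    displacement of the candidate night's mean from the baseline mean, in
    baseline standard-deviation units; |score| > ``threshold`` flags the
    night as anomalous. Both suppressed rest (unusually high nocturnal
    activity, the reported pre-earthquake pattern) and unusually silent
    nights trigger via the absolute value.

    This displacement statistic is this package's operational definition
    of "nocturnal rest-phase suppression"; no standard statistic exists
    for it.
    """
    base = np.asarray(baseline_night_means, dtype=float)
    if base.size < min_baseline_nights:
        raise CatalogError(
            f"no baseline: {base.size} reference nights, need {min_baseline_nights}"
        )
    sd = float(base.std(ddof=1))
    if sd == 0.0:
        raise CatalogError("degenerate baseline: zero variance across nights")
    score = float((np.mean(night_values) - base.mean()) / sd)
    return bool(abs(score) > threshold), score
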
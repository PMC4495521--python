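"""Calibration of the raw activity sum onto the manual 0-7 category scale.

Manual scoring: three independent operators each watch a short clip every
10 minutes and assign one of eight activity categories (0 = no ants on the
mound top ... 6 = crowded, 7 = sunbathing). The consensus category C(t) is
the rounded mean of the three scores, giving 144 consensus values per day.

Automatic calibration: over a fit window of about 2-3 weeks, raw activity
sums are paired with the consensus categories and split by sensor mode
into a daytime set S_d and a nighttime set S_n. A first-order polynomial
p_d is least-squares fitted to S_d and a second-order polynomial p_n to
S_n, minimizing the root-mean-squared difference between C(t) and
p(A(t)). The fitted polynomials map any raw sum to a continuous activity
index directly comparable to the manual categories; a 10-minute temporal
median filter then suppresses residual image noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from math import floor
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .activity import ActivitySeries
from .frame_stream import SensorMode

N_CATEGORIES = 8  # categories 0..7; 7 is the early-spring sunbathing state


class CalibrationError(ValueError):
    pass


@dataclass
class AnnotationRecord:
    """One manual-scoring window: three operator scores and their consensus."""

    timestamp: datetime  # window start, UTC
    operator_scores: tuple[int, int, int]
    consensus: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.consensus is None:
            self.consensus = aggregate_operator_scores(self.operator_scores)
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)


def aggregate_operator_scores(scores) -> int:
    """Consensus category: round-half-up of the mean of three 0-7 scores."""
    scores = tuple(int(s) for s in scores)
    if len(scores) != 3:
        raise CalibrationError("exactly three operator scores required")
    if any(s < 0 or s >= N_CATEGORIES for s in scores):
        raise CalibrationError(f"invalid category in {scores}")
    return int(floor(sum(scores) / 3.0 + 0.5))


def schedule_manual_windows(
    day: date | datetime,
    cadence_minutes: int = 10,
    window_seconds: int = 60,
    span_hours: float = 24.0,
) -> list[tuple[datetime, int]]:
    """Scoring-window schedule: (start_utc, length_s) every ``cadence_minutes``.

    A full 24-h day at the default 10-min cadence yields 144 windows at
    00:00, 00:10, ..., 23:50 UTC.
    """
    if cadence_minutes <= 0:
        raise CalibrationError("invalid cadence")
    if isinstance(day, datetime):
        start = day if day.tzinfo else day.replace(tzinfo=timezone.utc)
    else:
        start = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    n = int(span_hours * 60 // cadence_minutes)
    return [
        (start + timedelta(minutes=i * cadence_minutes), window_seconds)
        for i in range(n)
    ]


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Annotations CSV: timestamp_utc + op1,op2,op3 (or a consensus column)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        ts = pd.Timestamp(row["timestamp_utc"]).to_pydatetime()
        if {"op1", "op2", "op3"} <= set(df.columns):
            records.append(
                AnnotationRecord(ts, (row["op1"], row["op2"], row["op3"]))
            )
        else:
            c = int(row["consensus"])
            records.append(AnnotationRecord(ts, (c, c, c), consensus=c))
    return records


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "timestamp_utc": [r.timestamp.isoformat() for r in records],
            "op1": [r.operator_scores[0] for r in records],
            "op2": [r.operator_scores[1] for r in records],
            "op3": [r.operator_scores[2] for r in records],
            "consensus": [r.consensus for r in records],
        }
    ).to_csv(path, index=False)


def pair_samples(
    series: ActivitySeries,
    annotations: list[AnnotationRecord],
    window_seconds: float = 600.0,
) -> tuple[list[tuple[float, int]], list[tuple[float, int]]]:
    """Pair each consensus category with the raw activity of its time slot.

    For each annotation window [t, t + window) the within-window median of
    raw samples is paired with C(t); samples flagged by failed registration
    are excluded, and the pair is assigned to S_d or S_n by the dominant
    sensor mode inside the window. Windows without usable samples emit no
    pair. The default window is the full 10-min slot between consecutive
    manual scores, so every automatic sample informs exactly one pair.
    """
    s_d: list[tuple[float, int]] = []
    s_n: list[tuple[float, int]] = []
    if not series.samples or not annotations:
        raise CalibrationError("no pairs: empty series or annotations")
    ts = np.array([s.timestamp.timestamp() for s in series.samples])
    for rec in annotations:
        t0 = rec.timestamp.timestamp()
        i0, i1 = np.searchsorted(ts, [t0, t0 + window_seconds])
        window = [
            s for s in series.samples[i0:i1] if s.registered_ok
        ]
        if not window:
            continue
        n_day = sum(1 for s in window if s.sensor_mode == "day")
        mode: SensorMode = "day" if n_day * 2 >= len(window) else "night"
        raws = [s.raw for s in window if s.sensor_mode == mode]
        pair = (float(np.median(raws)), rec.consensus)
        (s_d if mode == "day" else s_n).append(pair)
    if not s_d and not s_n:
        raise CalibrationError("no pairs: no time overlap")
    return s_d, s_n


@dataclass
class CalibrationModel:
    """Per-mode polynomial maps from raw activity to the 0-7 index.

    Coefficients are in descending powers (numpy.polyfit convention):
    ``day_coeffs = (a1, a0)`` for p_d(x) = a1*x + a0 and
    ``night_coeffs = (b2, b1, b0)`` for p_n(x) = b2*x^2 + b1*x + b0.
    """

    day_coeffs: tuple[float, float] | None
    night_coeffs: tuple[float, float, float] | None
    fit_window: tuple[datetime, datetime] | None = None
    rms_day: float = float("nan")
    rms_night: float = float("nan")
    n_day: int = 0
    n_night: int = 0

    def coeffs(self, mode: SensorMode):
        c = self.day_coeffs if mode == "day" else self.night_coeffs
        if c is None:
            raise CalibrationError(f"no model for mode {mode!r}")
        return np.asarray(c, dtype=float)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "day": None if self.day_coeffs is None else list(self.day_coeffs),
            "night": None if self.night_coeffs is None else list(self.night_coeffs),
            "fit_window": None
            if self.fit_window is None
            else [t.isoformat() for t in self.fit_window],
            "rms_day": self.rms_day,
            "rms_night": self.rms_night,
            "n_day": self.n_day,
            "n_night": self.n_night,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        window = d.get("fit_window")
        return cls(
            day_coeffs=None if d["day"] is None else tuple(d["day"]),
            night_coeffs=None if d["night"] is None else tuple(d["night"]),
            fit_window=None
            if window is None
            else tuple(datetime.fromisoformat(t) for t in window),
            rms_day=d.get("rms_day", float("nan")),
            rms_night=d.get("rms_night", float("nan")),
            n_day=d.get("n_day", 0),
            n_night=d.get("n_night", 0),
        )


def _polyfit_mode(pairs, degree: int):
    a = np.array([p[0] for p in pairs], dtype=float)
    c = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(a) == 0:
        raise CalibrationError("rank deficient: all raw activities equal")
    coeffs = np.polyfit(a, c, degree)
    rms = float(np.sqrt(np.mean((np.polyval(coeffs, a) - c) ** 2)))
    return tuple(coeffs), rms


def fit_calibration(
    s_d: list[tuple[float, int]],
    s_n: list[tuple[float, int]],
    fit_window: tuple[datetime, datetime] | None = None,
) -> CalibrationModel:
    """Least-squares polynomial fits: degree 1 for day, degree 2 for night.

    Each mode needs at least degree + 2 pairs; a mode with too few pairs is
    left unfitted rather than failing the other.
    """
    model = CalibrationModel(None, None, fit_window=fit_window)
    if len(s_d) >= 3:
        model.day_coeffs, model.rms_day = _polyfit_mode(s_d, 1)
        model.n_day = len(s_d)
    if len(s_n) >= 4:
        model.night_coeffs, model.rms_night = _polyfit_mode(s_n, 2)
        model.n_night = len(s_n)
    if model.day_coeffs is None and model.night_coeffs is None:
        raise CalibrationError("insufficient pairs for either mode")
    return model


def apply_calibration(model: CalibrationModel, sample) -> float:
    """Continuous activity index p_mode(raw), clamped to [0, 7], unrounded."""
    value = float(np.polyval(model.coeffs(sample.sensor_mode), sample.raw))
    return float(np.clip(value, 0.0, N_CATEGORIES - 1))


def calibrate_series(model: CalibrationModel, series: ActivitySeries) -> pd.Series:
    """Calibrated index for every sample, as a UTC-indexed pandas Series."""
    values = [apply_calibration(model, s) for s in series.samples]
    idx = pd.DatetimeIndex([s.timestamp for s in series.samples])
    out = pd.Series(values, index=idx, name="index")
    out.attrs["sensor_mode"] = [s.sensor_mode for s in series.samples]
    return out


def median_filter_series(
    series: pd.Series, window_minutes: float = 10.0
) -> pd.Series:
    """Centered temporal median filter over a +-window/2 neighborhood.

    The window is defined on timestamps (inclusive at both ends), so
    irregular sampling and edge truncation are handled naturally; at the
    series edges the window simply contains fewer samples.
    """
    if len(series) == 0:
        return series.copy()
    t = series.index.view("int64") / 1e9
    v = series.to_numpy(dtype=float)
    half = window_minutes * 60.0 / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    out = np.array([np.median(v[a:b]) for a, b in zip(lo, hi)])
    filtered = pd.Series(out, index=series.index, name=series.name)
    filtered.attrs = dict(series.attrs)
    return filtered


def count_activity_peaks(series: pd.Series, prominence: float = 1.0) -> int:
    """Number of prominent local maxima in a (filtered) daily index curve.

    A peak counts when it rises at least ``prominence`` index units above
    the saddle separating it from a higher peak (topological persistence,
    computed by activating samples from the highest down and merging
    components with union-find). This screens the shot-to-shot wiggle of
    the continuous index so that the count reflects the shape of the
    daily routine (the normal routine is M-shaped: midday and
    late-afternoon maxima), and it is insensitive to the plateaus and
    micro-dips that the clamp at index 7 produces at flattened peak tops.
    """
    v = series.to_numpy(dtype=float)
    n = len(v)
    if n == 0:
        return 0
    parent = np.full(n, -1, dtype=np.int64)  # -1 = not yet activated
    birth: dict[int, float] = {}

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    count = 0
    order = np.argsort(-v, kind="stable")
    for i in order:
        parent[i] = i
        birth[i] = v[i]
        for nb in (i - 1, i + 1):
            if 0 <= nb < n and parent[nb] != -1:
                ra, rb = find(i), find(nb)
                if ra == rb:
                    continue
                # the younger (lower-birth) component dies at this saddle
                keep_root, die_root = (
                    (ra, rb) if birth[ra] >= birth[rb] else (rb, ra)
                )
                if birth[die_root] - v[i] >= prominence:
                    count += 1
                parent[die_root] = keep_root
    # the surviving component: the global maximum
    global_root = find(int(order[0]))
    if birth[global_root] - v[int(order[-1])] >= prominence:
        count += 1
    return count
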
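"""Ground-truthed synthetic inputs for every pipeline stage.

No public archive of the mound-camera recordings exists, so the pipeline
is exercised on synthetic scenes that reproduce the statistical structure
the method assumes: a static textured background; ants as small
high-contrast dots (bright on the dark mound by day, dark on the bright
near-infrared grass by night — the differencing is contrast-sign
agnostic and the generator deliberately exercises both signs); per-mode
i.i.d. Gaussian sensor noise; global integer camera jitter; a day/night
sensor switch at fixed wall-clock times; and a daily routine schedule for
the number of active ants (the normal routine is M-shaped, with midday
and late-afternoon peaks and a near-zero nocturnal rest phase).

Every generator is a pure function of its configuration and seed; the
per-frame ant positions, applied jitter and scheduled counts are returned
as ground truth so tests can compare pipeline output against what was
actually injected. What the scenes do not emulate: photorealistic ants,
grass motion, illumination drift, rain on the lens — conclusions from
these tests are about the algorithmic chain, not about field robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .activity import MoundMask
from .calibration import AnnotationRecord, N_CATEGORIES, aggregate_operator_scores
from .frame_stream import FrameRecord, FrameSequence, SensorMode
from .quake_catalog import QuakeEvent, StationLocation, destination_point

DAY_START_HOUR = 6.0    # color sensor active 06:00-20:00 UTC
DAY_END_HOUR = 20.0

#: Background intensity levels: dark mound material by day, bright
#: chlorophyll-reflecting grass under near-infrared illumination by night.
DAY_BG_LEVEL = 90.0
NIGHT_BG_LEVEL = 170.0
BG_TEXTURE_SD = 18.0


class SynthesisError(ValueError):
    pass


def make_ellipse_mask(height: int, width: int, fraction: float = 0.72) -> MoundMask:
    """Central elliptical mound mask with semi-axes ``fraction/2`` of the frame."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    a, b = fraction * height / 2.0, fraction * width / 2.0
    return MoundMask(((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0)


@dataclass
class SceneConfig:
    height: int = 48
    width: int = 64
    n_ants: Sequence[float] | float = 5.0  # per-frame schedule or constant
    n_frames: int = 60
    ant_size: int = 2          # ants drawn as size x size squares
    ant_contrast: float = 80.0
    speed: int = 3             # max step per frame, px (>= ant_size: full turnover)
    noise_sd_day: float = 2.0
    noise_sd_night: float = 3.0
    jitter_px: int = 0         # uniform integer camera offset in [-j, j]^2
    cadence: float = 10.0
    start: datetime = field(
        default_factory=lambda: datetime(2010, 6, 1, tzinfo=timezone.utc)
    )
    mask: MoundMask | None = None  # default: central ellipse
    seed: int = 0

    def resolved_mask(self) -> MoundMask:
        return self.mask or make_ellipse_mask(self.height, self.width)

    def schedule(self) -> np.ndarray:
        if np.isscalar(self.n_ants):
            return np.full(self.n_frames, float(self.n_ants))
        sched = np.asarray(self.n_ants, dtype=float)
        if len(sched) != self.n_frames:
            raise SynthesisError("n_ants schedule length != n_frames")
        return sched


@dataclass
class SceneTruth:
    """What was actually injected, frame by frame."""

    ant_positions: list[np.ndarray]   # (k, 2) int scene coords per frame
    jitter: np.ndarray                # (n_frames, 2) int (dy, dx) offsets
    n_ants: np.ndarray                # scheduled (rounded) counts per frame
    modes: list[SensorMode]


def sensor_mode_at(t: datetime) -> SensorMode:
    h = t.hour + t.minute / 60.0 + t.second / 3600.0
    return "day" if DAY_START_HOUR <= h < DAY_END_HOUR else "night"


def _make_texture(rng: np.random.Generator, shape, level: float) -> np.ndarray:
    raw = gaussian_filter(rng.standard_normal(shape), sigma=1.2)
    raw *= BG_TEXTURE_SD / raw.std()
    return np.clip(level + raw, 0, 255)


def generate_video(config: SceneConfig) -> tuple[FrameSequence, SceneTruth]:
    """Render a synthetic mound scene; deterministic given ``config.seed``.

    Ants perform a reflected random walk inside the eroded mound mask so
    that every ant square stays within the mask; each active ant moves
    every frame (a zero step is re-drawn), so the injected per-frame count
    is faithfully reflected in the difference images. Camera jitter is a
    per-frame global integer translation of the whole scene.
    """
    rng = np.random.default_rng(config.seed)
    h, w, j = config.height, config.width, config.jitter_px
    mask = config.resolved_mask()
    if mask.mask.shape != (h, w):
        raise SynthesisError("mask geometry does not match scene")

    margin = config.ant_size + 1
    walkable = binary_erosion(mask.mask, iterations=margin) if margin else mask.mask
    allowed = np.argwhere(walkable)
    if len(allowed) == 0:
        raise SynthesisError("infeasible scene: ants larger than mask region")
    allowed_set = {tuple(p) for p in allowed}

    schedule = np.rint(config.schedule()).astype(int)
    n_max = int(schedule.max())
    positions = allowed[rng.integers(0, len(allowed), size=max(n_max, 1))].copy()

    # scene canvases, padded so jitter is an exact translation
    pad = j
    canvas_shape = (h + 2 * pad, w + 2 * pad)
    bg = {
        "day": _make_texture(rng, canvas_shape, DAY_BG_LEVEL),
        "night": _make_texture(rng, canvas_shape, NIGHT_BG_LEVEL),
    }
    noise_sd = {"day": config.noise_sd_day, "night": config.noise_sd_night}

    frames: list[FrameRecord] = []
    truth_pos: list[np.ndarray] = []
    modes: list[SensorMode] = []
    jitter = (
        rng.integers(-j, j + 1, size=(config.n_frames, 2))
        if j > 0
        else np.zeros((config.n_frames, 2), dtype=int)
    )

    s = config.ant_size
    for i in range(config.n_frames):
        t = config.start + timedelta(seconds=i * config.cadence)
        mode = sensor_mode_at(t)
        k = schedule[i]
        # move every active ant by a nonzero step, staying inside the mask
        for a in range(k):
            for _ in range(8):
                step = rng.integers(-config.speed, config.speed + 1, size=2)
                if not step.any():
                    continue
                cand = positions[a] + step
                if tuple(cand) in allowed_set:
                    positions[a] = cand
                    break

        canvas = bg[mode].copy()
        sign = 1.0 if mode == "day" else -1.0  # bright by day, dark by night
        for a in range(k):
            r, c = positions[a] + pad
            canvas[r : r + s, c : c + s] = np.clip(
                bg[mode][r : r + s, c : c + s] + sign * config.ant_contrast, 0, 255
            )

        dy, dx = jitter[i]
        frame = canvas[pad + dy : pad + dy + h, pad + dx : pad + dx + w]
        if noise_sd[mode] > 0:
            frame = frame + rng.normal(0.0, noise_sd[mode], size=frame.shape)
        intensity = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        frames.append(FrameRecord(t, mode, intensity, source_id="SynthCam"))
        truth_pos.append(positions[:k].copy())
        modes.append(mode)

    seq = FrameSequence(frames, cadence=config.cadence)
    return seq, SceneTruth(truth_pos, jitter, schedule, modes)


ProfileShape = Literal["M_shaped", "flat", "suppressed_night"]


def generate_daily_profile(
    shape: ProfileShape,
    cadence_s: float = 10.0,
    start: datetime | None = None,
    span_hours: float = 24.0,
    max_ants: float = 12.0,
    flat_level: float = 4.0,
    suppression_origin_hour: float = 2.0,
    suppression_pre_hours: float = 6.0,
    suppression_post_hours: float = 2.0,
    suppression_level: float = 6.0,
) -> tuple[list[datetime], np.ndarray]:
    """Expected-ant-count schedule over a day at the analysis cadence.

    ``M_shaped`` is the normal daily routine: activity rises from dawn,
    peaks at midday and again in the late afternoon, and falls to a
    near-zero nocturnal rest phase. ``suppressed_night`` starts from the
    M-shape and forces the nocturnal level up within a window around a
    configured origin hour — the pre-earthquake anomaly pattern, in which
    the nocturnal rest phase is suppressed. ``flat`` is a constant control.
    """
    if start is None:
        start = datetime(2010, 6, 1, tzinfo=timezone.utc)
    n = int(round(span_hours * 3600.0 / cadence_s))
    times = [start + timedelta(seconds=i * cadence_s) for i in range(n)]
    hours = np.array(
        [(t - start).total_seconds() / 3600.0 % 24.0 + start.hour for t in times]
    ) % 24.0

    if shape == "flat":
        return times, np.full(n, float(flat_level))

    def m_curve(h: np.ndarray) -> np.ndarray:
        envelope = 1.0 / (1.0 + np.exp(-(h - DAY_START_HOUR) / 0.7))
        envelope *= 1.0 / (1.0 + np.exp(-(DAY_END_HOUR - h) / 0.7))
        bumps = np.exp(-0.5 * ((h - 12.0) / 1.5) ** 2)
        bumps += 0.9 * np.exp(-0.5 * ((h - 16.5) / 1.5) ** 2)
        return max_ants * envelope * bumps / 1.02

    values = m_curve(hours)
    if shape == "M_shaped":
        return times, values
    if shape == "suppressed_night":
        rel = (hours - suppression_origin_hour + 12.0) % 24.0 - 12.0
        in_window = (rel >= -suppression_pre_hours) & (rel <= suppression_post_hours)
        values = np.where(in_window, np.maximum(values, suppression_level), values)
        return times, values
    raise SynthesisError(f"unknown profile shape {shape!r}")


def categories_from_profile(
    window_starts: list[datetime],
    profile_times: list[datetime],
    profile_values: np.ndarray,
    window_seconds: float = 600.0,
    max_ants: float | None = None,
) -> list[int]:
    """Ground-truth manual categories: the window-mean count mapped to 0-7."""
    if max_ants is None:
        max_ants = float(np.max(profile_values)) or 1.0
    t = np.array([p.timestamp() for p in profile_times])
    cats = []
    for w in window_starts:
        t0 = w.timestamp()
        sel = (t >= t0) & (t < t0 + window_seconds)
        level = profile_values[sel].mean() if sel.any() else 0.0
        cats.append(int(np.clip(round(7.0 * level / max_ants), 0, N_CATEGORIES - 1)))
    return cats


def generate_operator_scores(
    window_starts: list[datetime],
    truth_categories: Sequence[int],
    disagreement: float = 0.2,
    seed: int = 0,
) -> list[AnnotationRecord]:
    """Three synthetic operators: the true category with i.i.d. +-1 slips.

    Each operator independently reports the true category, perturbed by
    +-1 (random sign, clipped to 0-7) with probability ``disagreement``;
    the consensus is recomputed from the three streams.
    """
    rng = np.random.default_rng(seed)
    records = []
    for t, c in zip(window_starts, truth_categories):
        scores = []
        for _ in range(3):
            s = int(c)
            if rng.random() < disagreement:
                s += int(rng.choice([-1, 1]))
            scores.append(int(np.clip(s, 0, N_CATEGORIES - 1)))
        records.append(
            AnnotationRecord(
                t, tuple(scores), consensus=aggregate_operator_scores(scores)
            )
        )
    return records


def generate_catalog(
    n_events: int,
    window: tuple[datetime, datetime],
    magnitude_range: tuple[float, float],
    station: StationLocation,
    radius_km: float,
    seed: int = 0,
) -> list[QuakeEvent]:
    """Synthetic catalog: events uniform in time, area-uniform in a disc
    around the station (distance ~ radius * sqrt(U), bearing uniform),
    magnitudes uniform in range."""
    rng = np.random.default_rng(seed)
    t0, t1 = window
    span = (t1 - t0).total_seconds()
    events = []
    for i in range(n_events):
        dist = radius_km * np.sqrt(rng.random())
        lon, lat = destination_point(
            (station.lon_deg, station.lat_deg), rng.uniform(0, 360), dist
        )
        events.append(
            QuakeEvent(
                label=f"synth-{i:03d}",
                origin_time=t0 + timedelta(seconds=float(rng.random() * span)),
                depth_km=float(rng.uniform(2.0, 15.0)),
                magnitude=float(rng.uniform(*magnitude_range)),
                lon_deg=lon,
                lat_deg=lat,
            )
        )
    return sorted(events, key=lambda e: e.origin_time)
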
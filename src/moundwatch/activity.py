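"""The raw activity index A(t): masked, noise-thresholded frame differencing.

Every 10 s the pixel-wise absolute difference ``D_uv(t) = |I_uv(t) -
I_uv(t - dt)|`` is formed between the current and the previous frame
(after registration). Moving ants show up as small bright spots in the
difference image. Pixel intensities of D that exceed three times the
sensor noise sigma are summed over the mound mask M; the sum A(t) is the
raw measure of how much is moving on top of the mound. The day (color)
and night (near-infrared) sensors have different noise levels and produce
systematically different images, so sigma is estimated per sensor mode and
no difference is computed across a day/night switch.

The noise scale sigma is estimated robustly from difference images in
motion-free territory: the median absolute difference of pixels *outside*
the mound mask, scaled by 1.4826 to be consistent with a Gaussian standard
deviation (the MAD rule; the difference of two frames with i.i.d. per-frame
noise sd s has sd s*sqrt(2), and that compound scale is what sigma
captures).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .frame_stream import FrameRecord, FrameSequence, SensorMode
from .registration import RegistrationParams, apply_shift, register_frame

#: Threshold multiplier: only difference intensities above NOISE_FACTOR * sigma
#: contribute to A(t).
NOISE_FACTOR = 3.0

#: MAD-to-Gaussian-sd consistency constant.
MAD_SCALE = 1.4826


class ActivityError(ValueError):
    pass


@dataclass
class MoundMask:
    """Boolean region M restricting the activity sum to the mound top."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ActivityError("mask must be 2-D")
        if not self.mask.any():
            raise ActivityError("mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_png(cls, path: str | Path) -> "MoundMask":
        import imageio.v3 as iio

        img = iio.imread(path)
        if img.ndim == 3:
            img = img[..., 0]
        return cls(img > 0)


@dataclass
class ActivitySample:
    timestamp: datetime
    raw: float                 # A(t) >= 0, integer-valued sum of 8-bit differences
    sensor_mode: SensorMode
    sigma: float
    registered_ok: bool = True


@dataclass
class ActivitySeries:
    samples: list[ActivitySample]
    cadence: float = 10.0

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_utc": [s.timestamp for s in self.samples],
                "raw": [s.raw for s in self.samples],
                "sensor_mode": [s.sensor_mode for s in self.samples],
                "sigma": [s.sigma for s in self.samples],
                "registered_ok": [s.registered_ok for s in self.samples],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def estimate_pixel_noise(
    sequence: FrameSequence,
    mask: MoundMask,
    mode: SensorMode,
    max_pairs: int = 50,
    min_pairs: int = 10,
) -> float:
    """Robust noise scale of the difference image for one sensor mode.

    sigma = 1.4826 * median(|D_uv|) over out-of-mask pixels, pooled across
    up to ``max_pairs`` consecutive same-mode frame pairs. Out-of-mask
    pixels are the best available motion-free reference: ants move inside
    the mask, so residual differences outside it are dominated by sensor
    noise.
    """
    frames = [f for f in sequence.frames if f.sensor_mode == mode]
    pairs = list(zip(frames, frames[1:]))
    if len(pairs) < min_pairs:
        raise ActivityError(
            f"insufficient data: {len(pairs)} {mode} frame pairs, need {min_pairs}"
        )
    if len(pairs) > max_pairs:
        idx = np.linspace(0, len(pairs) - 1, max_pairs).astype(int)
        pairs = [pairs[i] for i in idx]
    outside = ~mask.mask
    diffs = [
        np.abs(b.intensity.astype(np.int16) - a.intensity.astype(np.int16))[outside]
        for a, b in pairs
    ]
    return float(MAD_SCALE * np.median(np.concatenate(diffs)))


def compute_raw_activity(
    previous: FrameRecord,
    current: FrameRecord,
    mask: MoundMask,
    sigma: float,
    valid: np.ndarray | None = None,
    registered_ok: bool = True,
    count_mode: bool = False,
) -> ActivitySample:
    """One activity sample from a registered, same-mode frame pair.

    raw = sum over (u, v) in M (and registration-valid) of D_uv(t) where
    D_uv(t) > 3 * sigma, with D the absolute inter-frame difference. The
    inequality is strict, so sigma = 0 admits every nonzero difference.
    The sum of 8-bit differences is an exact integer.

    With ``count_mode`` the suprathreshold pixels are counted instead of
    summing their intensities (off by default: the index is defined as an
    intensity sum).
    """
    if previous.sensor_mode != current.sensor_mode:
        raise ActivityError("sensor mode mismatch across the frame pair")
    if previous.intensity.shape != mask.mask.shape:
        raise ActivityError("inconsistent geometry: mask does not match frames")
    d = np.abs(
        current.intensity.astype(np.int16) - previous.intensity.astype(np.int16)
    )
    region = mask.mask if valid is None else (mask.mask & valid)
    dm = d[region]
    supra = dm > NOISE_FACTOR * sigma
    raw = int(supra.sum()) if count_mode else int(dm[supra].sum())
    return ActivitySample(
        timestamp=current.timestamp,
        raw=raw,
        sensor_mode=current.sensor_mode,
        sigma=sigma,
        registered_ok=registered_ok,
    )


def compute_activity_series(
    sequence: FrameSequence,
    mask: MoundMask,
    sigma: dict[SensorMode, float] | None = None,
    register: bool = True,
    registration_params: RegistrationParams = RegistrationParams(),
) -> ActivitySeries:
    """Full activity series: one sample per consecutive same-mode frame pair.

    Per pair, the current frame is registered onto the previous one (shift
    compensated, uncovered border excluded) and the thresholded difference
    sum is taken over the mask. Pairs spanning a sensor switch or a dropout
    gap yield no sample. ``sigma`` maps sensor mode to noise scale; modes
    not supplied are auto-estimated from the sequence (falling back to 0
    when too few frames exist for estimation).
    """
    sequence.validate()
    sigma = dict(sigma) if sigma else {}
    for mode in ("day", "night"):
        if mode not in sigma:
            try:
                sigma[mode] = estimate_pixel_noise(sequence, mask, mode)
            except ActivityError:
                sigma[mode] = 0.0

    max_gap = 3.0 * sequence.cadence
    samples = []
    for prev, cur in zip(sequence.frames, sequence.frames[1:]):
        if cur.sensor_mode != prev.sensor_mode:
            continue  # day/night boundary: sensors not comparable
        if (cur.timestamp - prev.timestamp).total_seconds() > max_gap:
            continue  # dropout
        if register:
            reg = register_frame(
                prev.intensity, cur.intensity, registration_params, mask=mask.mask
            )
            aligned, valid = apply_shift(
                cur.intensity, (-reg.shift[0], -reg.shift[1])
            )
            cur_use = FrameRecord(
                cur.timestamp, cur.sensor_mode, aligned, cur.source_id
            )
            samples.append(
                compute_raw_activity(
                    prev,
                    cur_use,
                    mask,
                    sigma[cur.sensor_mode],
                    valid=valid,
                    registered_ok=reg.ok,
                )
            )
        else:
            samples.append(
                compute_raw_activity(prev, cur, mask, sigma[cur.sensor_mode])
            )
    return ActivitySeries(samples, cadence=sequence.cadence)
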
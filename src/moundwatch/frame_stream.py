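"""Ingestion of timestamped frame sequences from a fixed mound camera.

The monitoring cameras carry two sensors: an RGB color sensor used at
daytime and a near-infrared sensor with active illumination used at night.
Every frame is reduced to a single-channel 8-bit intensity grid ``I_uv(t)``
and labeled with its sensor mode, because the two sensors produce
systematically different images and are processed separately downstream.

Frames arrive either as a directory of still images whose filenames encode
a UTC timestamp (``<anything>_YYYYMMDDTHHMMSSZ.png``) or via a CSV manifest
with explicit per-frame paths, timestamps and optional sensor-mode tags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

SensorMode = Literal["day", "night"]

#: Rec. 601 luminance weights used to collapse day RGB frames to intensity.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Gaps longer than this multiple of the nominal cadence count as dropouts.
DROPOUT_FACTOR = 3.0

_TS_RE = re.compile(r"(\d{8}T\d{6})Z")
_TS_FMT = "%Y%m%dT%H%M%S"


class FrameStreamError(ValueError):
    """Raised for unreadable, empty or geometrically inconsistent input."""


@dataclass
class FrameRecord:
    """One timestamped single-channel frame.

    ``intensity`` is the 8-bit grid the difference analysis consumes; the
    original channel count survives only through ``sensor_mode``.
    """

    timestamp: datetime
    sensor_mode: SensorMode
    intensity: np.ndarray  # uint8, H x W
    source_id: str = "AntCam1"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise FrameStreamError("unsupported image: intensity must be 2-D")
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)


@dataclass
class FrameSequence:
    """Time-ordered frames at a nominal cadence (default 10 s).

    ``dropouts`` lists ``(timestamp_before_gap, gap_seconds)`` for every
    inter-frame gap exceeding ``DROPOUT_FACTOR`` times the cadence;
    ``rejected`` lists input paths whose timestamps could not be parsed.
    """

    frames: list[FrameRecord]
    cadence: float = 10.0
    dropouts: list[tuple[datetime, float]] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].intensity.shape

    def validate(self) -> None:
        if not self.frames:
            raise FrameStreamError("no frames")
        shapes = {f.intensity.shape for f in self.frames}
        if len(shapes) > 1:
            raise FrameStreamError("inconsistent geometry")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise FrameStreamError("timestamps not strictly increasing")


def to_intensity(raw_image: np.ndarray, sensor_mode: SensorMode) -> np.ndarray:
    """Collapse a 1- or 3-channel 8-bit image to a single intensity grid.

    Night (near-infrared) frames are single-channel already and pass
    through unchanged; day RGB frames are reduced with the fixed luminance
    weights (0.299, 0.587, 0.114) and rounded back to uint8. A 2-D input is
    returned as-is for either mode, so the function is idempotent.
    """
    img = np.asarray(raw_image)
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim == 3 and img.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        return np.rint(img.astype(np.float64) @ w).clip(0, 255).astype(np.uint8)
    raise FrameStreamError("unsupported image: channel count not in {1, 3}")


def classify_sensor_mode(
    metadata_tag: str | None, raw_image: np.ndarray
) -> SensorMode:
    """Label a frame day/night; an explicit metadata tag wins.

    Tags containing "ir"/"night" map to night and "day"/"color"/"rgb" to
    day. Without a tag, the channel-count heuristic applies: 3 channels
    (color sensor) means day, 1 channel (NIR sensor) means night.
    """
    if metadata_tag:
        tag = metadata_tag.strip().lower()
        if tag in {"night", "ir", "nir", "infrared"}:
            return "night"
        if tag in {"day", "color", "colour", "rgb"}:
            return "day"
        raise FrameStreamError(f"unrecognized sensor tag: {metadata_tag!r}")
    img = np.asarray(raw_image)
    return "day" if img.ndim == 3 and img.shape[2] == 3 else "night"


def parse_frame_timestamp(name: str) -> datetime:
    """Extract a UTC timestamp of the form YYYYMMDDTHHMMSSZ from a filename."""
    m = _TS_RE.search(name)
    if m is None:
        raise FrameStreamError(f"no parseable timestamp in {name!r}")
    return datetime.strptime(m.group(1), _TS_FMT).replace(tzinfo=timezone.utc)


def _find_dropouts(
    timestamps: Sequence[datetime], cadence: float
) -> list[tuple[datetime, float]]:
    out = []
    for a, b in zip(timestamps, timestamps[1:]):
        gap = (b - a).total_seconds()
        if gap > DROPOUT_FACTOR * cadence:
            out.append((a, gap))
    return out


def read_frame_sequence(
    path: str | Path, cadence: float = 10.0, source_id: str = "AntCam1"
) -> FrameSequence:
    """Read a frame directory or CSV manifest into a :class:`FrameSequence`.

    A directory is scanned for PNG/JPEG/TIFF files with filename
    timestamps; a ``.csv`` path is read as a manifest with columns
    ``path``, ``timestamp_utc`` and optional ``sensor_mode``. Frames are
    returned sorted by timestamp with dropouts flagged; files without a
    parseable timestamp are rejected and reported, not fatal.
    """
    path = Path(path)
    entries: list[tuple[datetime, Path, str | None]] = []
    rejected: list[str] = []

    if path.suffix.lower() == ".csv":
        manifest = pd.read_csv(path)
        for _, row in manifest.iterrows():
            img_path = Path(row["path"])
            if not img_path.is_absolute():
                img_path = path.parent / img_path
            try:
                ts = pd.Timestamp(row["timestamp_utc"]).to_pydatetime()
            except (ValueError, TypeError):
                rejected.append(str(row["path"]))
                continue
            if ts.tzinfo is None:
                ts = ts.replace(tzinfo=timezone.utc)
            tag = row.get("sensor_mode")
            entries.append((ts, img_path, None if pd.isna(tag) else str(tag)))
    elif path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
        )
        for p in files:
            try:
                entries.append((parse_frame_timestamp(p.name), p, None))
            except FrameStreamError:
                rejected.append(p.name)
    else:
        raise FrameStreamError(f"not a frame directory or manifest: {path}")

    if not entries:
        raise FrameStreamError("no frames")

    entries.sort(key=lambda e: e[0])
    frames = []
    for ts, img_path, tag in entries:
        raw = iio.imread(img_path)
        mode = classify_sensor_mode(tag, raw)
        frames.append(
            FrameRecord(ts, mode, to_intensity(raw, mode), source_id=source_id)
        )

    seq = FrameSequence(
        frames,
        cadence=cadence,
        dropouts=_find_dropouts([f.timestamp for f in frames], cadence),
        rejected=rejected,
    )
    seq.validate()
    return seq


def write_frame_sequence(sequence: FrameSequence, out_dir: str | Path) -> Path:
    """Write frames as PNGs plus a manifest CSV; returns the manifest path.

    PNG is lossless, so write-then-read round-trips every pixel and
    timestamp bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in sequence.frames:
        stamp = f.timestamp.strftime(_TS_FMT) + "Z"
        name = f"{f.source_id}_{stamp}.png"
        iio.imwrite(out_dir / name, f.intensity)
        rows.append(
            {
                "path": name,
                "timestamp_utc": f.timestamp.isoformat(),
                "sensor_mode": f.sensor_mode,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
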
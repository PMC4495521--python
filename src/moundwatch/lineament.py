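"""Preferential alignment directions of mound positions (Hough analysis).

Red wood ant mounds line up along gas-permeable faults; on a map of mound
positions those lineaments appear as sets of nearly collinear points. A
Hough transform over the point set accumulates support in (rho, theta)
cells — each cell a candidate line — and the per-angle support of
well-populated cells gives an orientation histogram over the axial range
[0, 180) degrees from North. Local maxima of the (circularly smoothed)
histogram are the preferential alignment directions; each mode is
summarized by the axial circular mean and standard deviation of its
member angles, weighted by support.

Angles are axial (a line at 10 degrees equals one at 190), so all circular
statistics operate on doubled angles. Geographic input is projected to a
local azimuthal-equidistant plane first; at the tens-of-kilometres scale
of a mound survey the planar treatment is standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, atan2, cos, degrees, radians, sin

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .quake_catalog import EARTH_RADIUS_KM


class LineamentError(ValueError):
    pass


@dataclass
class OrientationMode:
    mean_deg: float   # axial circular mean, degrees from North in [0, 180)
    sd_deg: float     # axial circular standard deviation, degrees
    support: float    # summed histogram mass of the mode's bins


@dataclass
class OrientationHistogram:
    bin_edges: np.ndarray  # angle bin edges over [0, 180], degrees
    counts: np.ndarray     # accumulated Hough support per angle bin
    modes: list[OrientationMode]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def project_azimuthal_equidistant(
    lonlat: np.ndarray, center: tuple[float, float] | None = None
) -> np.ndarray:
    """Project (lon, lat) degrees to local planar (x_east, y_north) km.

    Azimuthal equidistant projection about ``center`` (default: the mean
    coordinate): distances and azimuths from the center are preserved,
    which is exactly what an orientation analysis needs.
    """
    pts = np.asarray(lonlat, dtype=float)
    if center is None:
        center = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    lon0, lat0 = radians(center[0]), radians(center[1])
    lon = np.radians(pts[:, 0])
    lat = np.radians(pts[:, 1])
    # great-circle distance and forward azimuth from the center
    c = np.arccos(
        np.clip(
            sin(lat0) * np.sin(lat)
            + cos(lat0) * np.cos(lat) * np.cos(lon - lon0),
            -1.0,
            1.0,
        )
    )
    az = np.arctan2(
        np.sin(lon - lon0) * np.cos(lat),
        cos(lat0) * np.sin(lat) - sin(lat0) * np.cos(lat) * np.cos(lon - lon0),
    )
    r = EARTH_RADIUS_KM * c
    return np.column_stack([r * np.sin(az), r * np.cos(az)])


def hough_orientation(
    points: np.ndarray,
    angle_bins: int = 180,
    rho_bin: float | None = None,
    min_support: int = 3,
) -> OrientationHistogram:
    """Point-set Hough transform summarized as an orientation histogram.

    ``points`` are planar (x_east, y_north). For every point and every
    candidate azimuth theta (measured from North/+y, clockwise towards
    East/+x, axial range [0, 180)), the signed offset of the line through
    the point at that azimuth is accumulated into a (theta, rho) cell.
    Cells reaching ``min_support`` points contribute their count to the
    angle histogram, so isolated point pairs do not register as lineaments.
    ``rho_bin`` defaults to 1/50 of the point-cloud diagonal.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise LineamentError("need at least two planar points")
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    if diag == 0:
        raise LineamentError("degenerate point set: all points identical")
    if rho_bin is None:
        rho_bin = diag / 50.0

    thetas_deg = (np.arange(angle_bins) + 0.5) * (180.0 / angle_bins)
    th = np.radians(thetas_deg)
    # A line with azimuth theta has direction (sin th, cos th); its normal
    # is (cos th, -sin th), so rho = x*cos(th) - y*sin(th).
    x = pts[:, 0][:, None]
    y = pts[:, 1][:, None]
    rho = x * np.cos(th)[None, :] - y * np.sin(th)[None, :]
    rho_idx = np.round(rho / rho_bin).astype(np.int64)

    counts = np.zeros(angle_bins)
    for j in range(angle_bins):
        _, cell_counts = np.unique(rho_idx[:, j], return_counts=True)
        counts[j] = cell_counts[cell_counts >= min_support].sum()

    edges = np.linspace(0.0, 180.0, angle_bins + 1)
    hist = OrientationHistogram(bin_edges=edges, counts=counts, modes=[])
    hist.modes = find_modes(hist)
    return hist


def _axial_mean_sd(angles_deg: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted circular mean/SD of axial angles via the doubled-angle trick."""
    w = weights / weights.sum()
    z = np.exp(2j * np.radians(angles_deg))
    m = complex((w * z).sum())
    mean = degrees(atan2(m.imag, m.real)) / 2.0 % 180.0
    r_bar = min(1.0, abs(m))
    if r_bar <= 0:
        return mean, 90.0
    sd = degrees(np.sqrt(-2.0 * np.log(r_bar))) / 2.0
    return mean, sd


def find_modes(
    histogram: OrientationHistogram,
    smoothing_bins: int = 7,
    prominence_frac: float = 0.15,
) -> list[OrientationMode]:
    """Partition the (circularly smoothed) histogram into orientation modes.

    Local maxima of the smoothed counts with a prominence of at least
    ``prominence_frac`` of the smoothed maximum seed the modes (prominence
    is evaluated on the circularly tiled histogram so axial wraparound is
    respected: a bump straddling 0/180 is a single mode). The axis is
    split at the minima between consecutive maxima, and each mode reports
    the support-weighted axial circular mean and SD of its member bins. A
    flat histogram has no modes.
    """
    counts = histogram.counts
    n = len(counts)
    if counts.sum() == 0 or np.ptp(counts) == 0:
        return []
    smooth = uniform_filter1d(counts, size=smoothing_bins, mode="wrap")
    if np.ptp(smooth) == 0:
        return []
    tiled = np.concatenate([smooth, smooth, smooth])
    tiled_peaks, _ = find_peaks(tiled, prominence=prominence_frac * smooth.max())
    peak_idx = np.unique(
        tiled_peaks[(tiled_peaks >= n) & (tiled_peaks < 2 * n)] - n
    )
    if peak_idx.size == 0:
        return []
    if peak_idx.size == 1:
        mean, sd = _axial_mean_sd(histogram.bin_centers, counts + 1e-12)
        return [OrientationMode(mean, sd, float(counts.sum()))]
    # boundaries: minimum of the smoothed histogram between consecutive peaks
    boundaries = []
    for a, b in zip(peak_idx, np.roll(peak_idx, -1)):
        seg = np.arange(a, b if b > a else b + n)
        seg_mod = seg % n
        boundaries.append(seg_mod[np.argmin(smooth[seg_mod])])
    modes = []
    for left, right in zip(np.roll(boundaries, 1), boundaries):
        seg = np.arange(left, right if right > left else right + n) % n
        w = counts[seg]
        if w.sum() <= 0:
            continue
        mean, sd = _axial_mean_sd(histogram.bin_centers[seg], w)
        modes.append(OrientationMode(mean, sd, float(w.sum())))
    modes.sort(key=lambda m: m.mean_deg)
    return modes
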
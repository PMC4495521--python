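"""Translation-only frame registration by normalized cross-correlation.

Wind moves the camera slightly between frames; an uncompensated global
shift of the whole scene would swamp the small difference signal left by
moving ants. Each frame is therefore registered onto its predecessor
before differencing. Interest points (high-gradient corners, taken outside
the mound mask so that ant motion cannot bias the estimate) are detected
on the reference frame, and the translation maximizing the mean normalized
cross-correlation of small patches around those points is selected over an
integer search window. A translation-only model suffices because the
camera is rigidly mounted and only sways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template, peak_local_max
from skimage.filters import sobel


@dataclass(frozen=True)
class RegistrationParams:
    max_shift: int = 10          # half-width of the shift search window, px
    min_score: float = 0.5       # mean NCC below this -> registration fails
    min_points: int = 5          # fewer usable interest points -> fails
    max_points: int = 40         # strongest corners kept
    patch_radius: int = 4        # NCC patch is (2r+1) x (2r+1)
    subpixel: bool = False       # parabolic refinement of the NCC peak


@dataclass
class RegistrationResult:
    shift: tuple[float, float]   # (dy, dx): displacement of current vs reference
    score: float                 # peak mean NCC in [-1, 1]
    n_points: int
    ok: bool


def detect_interest_points(
    grid: np.ndarray,
    mask: np.ndarray | None = None,
    params: RegistrationParams = RegistrationParams(),
) -> np.ndarray:
    """Corner-like interest points on ``grid``, as an (N, 2) array of (row, col).

    Points inside ``mask`` (the mound region, where ants move) are excluded,
    as are points too close to the border for a full search window.
    """
    img = np.asarray(grid, dtype=np.float64)
    margin = params.patch_radius + params.max_shift + 1
    response = sobel(img)  # gradient magnitude
    if mask is not None:
        response[np.asarray(mask, bool)] = 0.0
    h, w = img.shape
    if h <= 2 * margin or w <= 2 * margin:
        return np.empty((0, 2), dtype=int)
    response[:margin] = response[h - margin :] = 0.0
    response[:, :margin] = response[:, w - margin :] = 0.0
    peaks = peak_local_max(
        response,
        min_distance=3,
        threshold_rel=0.05,
        num_peaks=params.max_points,
    )
    return peaks.reshape(-1, 2)


def _parabolic_offset(v_minus: float, v_0: float, v_plus: float) -> float:
    denom = v_minus - 2.0 * v_0 + v_plus
    if denom >= 0:  # not a local maximum of a concave parabola
        return 0.0
    return float(np.clip(0.5 * (v_minus - v_plus) / denom, -0.5, 0.5))


def register_frame(
    reference: np.ndarray,
    current: np.ndarray,
    params: RegistrationParams = RegistrationParams(),
    mask: np.ndarray | None = None,
) -> RegistrationResult:
    """Estimate the global translation of ``current`` relative to ``reference``.

    Returns the shift ``(dy, dx)`` such that scene content at (r, c) in the
    reference appears at (r + dy, c + dx) in the current frame. On failure
    (too few interest points or a correlation peak below ``min_score``) the
    shift falls back to (0, 0) with ``ok=False`` so the frame survives but
    the derived activity sample can be flagged.
    """
    ref = np.asarray(reference, dtype=np.float64)
    cur = np.asarray(current, dtype=np.float64)
    if ref.shape != cur.shape:
        raise ValueError("inconsistent geometry")

    points = detect_interest_points(ref, mask=mask, params=params)
    if len(points) < params.min_points:
        return RegistrationResult((0.0, 0.0), 0.0, len(points), False)

    r, s = params.patch_radius, params.max_shift
    # Mean NCC surface over all candidate integer shifts in [-s, s]^2.
    acc = np.zeros((2 * s + 1, 2 * s + 1))
    for row, col in points:
        template = ref[row - r : row + r + 1, col - r : col + r + 1]
        if template.std() == 0:
            continue
        search = cur[row - r - s : row + r + s + 1, col - r - s : col + r + s + 1]
        acc += match_template(search, template, pad_input=False)
    acc /= len(points)

    iy, ix = np.unravel_index(np.argmax(acc), acc.shape)
    score = float(acc[iy, ix])
    dy, dx = float(iy - s), float(ix - s)
    if params.subpixel:
        if 0 < iy < 2 * s:
            dy += _parabolic_offset(acc[iy - 1, ix], acc[iy, ix], acc[iy + 1, ix])
        if 0 < ix < 2 * s:
            dx += _parabolic_offset(acc[iy, ix - 1], acc[iy, ix], acc[iy, ix + 1])

    if score < params.min_score:
        return RegistrationResult((0.0, 0.0), score, len(points), False)
    return RegistrationResult((dy, dx), score, len(points), True)


def apply_shift(
    grid: np.ndarray, shift: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Translate ``grid`` by integer ``shift`` = (dy, dx).

    Returns ``(shifted, valid)`` where ``valid`` marks pixels actually
    covered by source data; the uncovered border introduced by the
    translation must be excluded from differencing. Non-integer shifts are
    rounded (differencing operates at integer resolution).
    """
    g = np.asarray(grid)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    shifted = np.zeros_like(g)
    valid = np.zeros(g.shape, dtype=bool)
    h, w = g.shape
    src = (slice(max(0, -dy), min(h, h - dy)), slice(max(0, -dx), min(w, w - dx)))
    dst = (slice(max(0, dy), min(h, h + dy)), slice(max(0, dx), min(w, w + dx)))
    shifted[dst] = g[src]
    valid[dst] = True
    return shifted, valid
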
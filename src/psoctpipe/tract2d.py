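"""Streamline tractography on 2-D axial orientation fields.

The tracker is FACT-style: the step direction at a point is the orientation
of the nearest pixel (optionally a doubled-angle bilinear interpolation),
with the sign chosen to continue the previous step.  Axial orientations
carry no intrinsic sign, so every seed spawns two half-tracks (one per
initial sign) that are merged.  Tracking terminates on leaving the mask or
field bounds, on an axial angle change between consecutive pixel
orientations above the angular threshold (default 45 degrees), on NaN
orientation, or at the length cap.  The trackable region is the white
matter, obtained by thresholding the retardance map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

__all__ = [
    "AxialOrientationField",
    "Streamline",
    "build_mask_from_retardance",
    "seed_grid",
    "track",
]


@dataclass
class AxialOrientationField:
    """Axial (180-degree periodic) orientation map with a trackable mask.

    ``theta`` is degrees in [0, 180) or NaN; the mask is forced false
    wherever theta is NaN.  Coordinates are (x, y) with x = column, y = row.
    """

    theta: np.ndarray
    mask: np.ndarray
    pixel_um: float = 10.0

    def __post_init__(self) -> None:
        if self.theta.shape != self.mask.shape:
            raise ValueError("theta and mask shapes differ")
        self.mask = self.mask & np.isfinite(self.theta)


@dataclass
class Streamline:
    """Ordered sub-pixel points (N, 2) in (x, y) pixel units."""

    points: np.ndarray
    length_px: float


def build_mask_from_retardance(
    retardance_map: np.ndarray,
    threshold: float | None = None,
    min_size: int = 50,
    hole_size: int = 50,
) -> np.ndarray:
    """White-matter mask: retardance >= threshold, then morphological cleanup.

    With ``threshold=None`` the threshold is chosen by Otsu's method on the
    finite retardance values (documented heuristic; myelinated white matter
    is the high-retardance mode).  Components smaller than ``min_size``
    pixels are removed and holes up to ``hole_size`` pixels are filled.
    """
    ret = np.asarray(retardance_map, dtype=float)
    if threshold is None:
        finite = ret[np.isfinite(ret)]
        if finite.size == 0 or np.ptp(finite) == 0:
            raise ValueError("cannot choose an Otsu threshold on a flat map")
        threshold = float(threshold_otsu(finite))
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = np.isfinite(ret) & (ret >= threshold)
    if min_size > 1:
        mask = remove_small_objects(mask, max_size=min_size - 1)
    if hole_size > 0:
        mask = remove_small_holes(mask, max_size=hole_size)
    return mask


def seed_grid(mask: np.ndarray, spacing_px: int) -> np.ndarray:
    """Regular (x, y) seed lattice intersected with the mask; (N, 2) floats."""
    if spacing_px < 1:
        raise ValueError("spacing_px must be >= 1")
    ys = np.arange(0, mask.shape[0], spacing_px)
    xs = np.arange(0, mask.shape[1], spacing_px)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    keep = mask[gy, gx]
    return np.stack([gx[keep], gy[keep]], axis=-1).astype(float)


def _axial_diff_deg(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _direction_nearest(field: AxialOrientationField, x: float, y: float):
    iy, ix = int(round(y)), int(round(x))
    ny, nx = field.theta.shape
    if not (0 <= iy < ny and 0 <= ix < nx) or not field.mask[iy, ix]:
        return None, None
    th = field.theta[iy, ix]
    if not np.isfinite(th):
        return None, None
    rad = np.deg2rad(th)
    return np.array([np.cos(rad), np.sin(rad)]), th


def _direction_bilinear(field: AxialOrientationField, x: float, y: float):
    ny, nx = field.theta.shape
    iy, ix = int(round(y)), int(round(x))
    if not (0 <= iy < ny and 0 <= ix < nx) or not field.mask[iy, ix]:
        return None, None
    x0 = int(np.clip(np.floor(x), 0, nx - 2))
    y0 = int(np.clip(np.floor(y), 0, ny - 2))
    fx, fy = x - x0, y - y0
    c = s = wtot = 0.0
    for (dy, dx, w) in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        th = field.theta[y0 + dy, x0 + dx]
        if np.isfinite(th) and field.mask[y0 + dy, x0 + dx] and w > 0:
            two = 2.0 * np.deg2rad(th)
            c += w * np.cos(two)
            s += w * np.sin(two)
            wtot += w
    if wtot == 0 or np.hypot(c, s) < 1e-12:
        return None, None
    th = np.mod(np.degrees(np.arctan2(s, c)), 360.0) / 2.0
    rad = np.deg2rad(th)
    return np.array([np.cos(rad), np.sin(rad)]), th


def _track_half(field, seed, sign, step_px, max_angle_deg, max_len_px, lookup):
    """One half-track from the seed; returns the list of points after it."""
    pts = []
    x, y = float(seed[0]), float(seed[1])
    d, th_prev = lookup(field, x, y)
    if d is None:
        return pts
    d = sign * d
    length = 0.0
    while length < max_len_px:
        x_new, y_new = x + step_px * d[0], y + step_px * d[1]
        d_new, th_new = lookup(field, x_new, y_new)
        if d_new is None:
            break
        if _axial_diff_deg(th_new, th_prev) > max_angle_deg:
            break
        if float(np.dot(d_new, d)) < 0:
            d_new = -d_new
        pts.append((x_new, y_new))
        x, y, d, th_prev = x_new, y_new, d_new, th_new
        length += step_px
    return pts


def track(
    field: AxialOrientationField,
    seeds: np.ndarray,
    step_px: float = 0.5,
    max_angle_deg: float = 45.0,
    min_len_px: float = 10.0,
    max_len_px: float = 1e4,
    mode: str = "nearest",
) -> list[Streamline]:
    """Bidirectional streamline tracking from seed points.

    ``mode`` selects the orientation lookup: ``"nearest"`` (FACT-style, the
    default) or ``"bilinear"`` (doubled-angle interpolation).  Seeds outside
    the mask are skipped with a warning.  Streamlines shorter than
    ``min_len_px`` are discarded.
    """
    if not 0 < step_px <= 1:
        raise ValueError("step_px must lie in (0, 1]")
    if not 0 < max_angle_deg <= 90:
        raise ValueError("max_angle_deg must lie in (0, 90]")
    lookup = {"nearest": _direction_nearest, "bilinear": _direction_bilinear}[mode]
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    out: list[Streamline] = []
    for seed in seeds:
        d0, _ = lookup(field, seed[0], seed[1])
        if d0 is None:
            warnings.warn(f"seed {tuple(seed)} outside trackable mask; skipped")
            continue
        fwd = _track_half(field, seed, +1.0, step_px, max_angle_deg, max_len_px, lookup)
        bwd = _track_half(field, seed, -1.0, step_px, max_angle_deg, max_len_px, lookup)
        pts = list(reversed(bwd)) + [(float(seed[0]), float(seed[1]))] + fwd
        length = step_px * (len(pts) - 1)
        if length >= min_len_px:
            out.append(Streamline(points=np.asarray(pts), length_px=length))
    return out
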
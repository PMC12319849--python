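"""En-face parameter maps, tile mosaicking and serial-section stacking.

Scalar volumes collapse to 2-D maps by NaN-ignoring depth averaging; the
axial orientation collapses to the centre of the peak 5-degree histogram
bin.  Tiles are fused by linear blending (weights ramp from the tile edge
over the overlap width and are normalized to sum to one); orientation maps
are blended on doubled-angle unit vectors so the 0/180 seam is handled
correctly.  Serial sections stack into a volume with the slice thickness
recorded as the section-axis spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterMapStack",
    "TileLayout",
    "SectionVolume",
    "enface_mean",
    "enface_orientation",
    "stitch",
    "stack_sections",
]


@dataclass
class ParameterMapStack:
    """Co-located en-face maps: mu_s (mm^-1), retardance (deg), axis (deg)."""

    mu_s_map: np.ndarray
    retardance_map: np.ndarray
    orientation_map: np.ndarray
    pixel_um: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    reflectivity_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {
            self.mu_s_map.shape,
            self.retardance_map.shape,
            self.orientation_map.shape,
        } | {m.shape for m in self.masks.values()}
        if self.reflectivity_map is not None:
            shapes.add(self.reflectivity_map.shape)
        if len(shapes) != 1:
            raise ValueError(f"all maps must share one shape, got {shapes}")
        theta = self.orientation_map
        ok = np.isnan(theta) | ((theta >= 0) & (theta < 180))
        if not ok.all():
            raise ValueError("orientation_map values must be in [0, 180) or NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu_s_map.shape


@dataclass
class TileLayout:
    """Tiles with nominal (y, x) pixel offsets and their overlap fraction."""

    tiles: list[tuple[ParameterMapStack, tuple[int, int]]]
    overlap_frac: float = 0.2

    def __post_init__(self) -> None:
        if not self.tiles:
            raise ValueError("layout must contain at least one tile")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must lie in [0, 1)")
        if any(o < 0 for _, off in self.tiles for o in off):
            raise ValueError("tile offsets must be non-negative")
        if len({t.pixel_um for t, _ in self.tiles}) != 1:
            raise ValueError("tiles must share a single pixel size")


@dataclass
class SectionVolume:
    """Stack of serial sections; axis 0 is the section (cut) axis."""

    mu_s: np.ndarray
    retardance: np.ndarray
    orientation: np.ndarray
    pixel_um: float
    slice_thickness_um: float


def enface_mean(volume: np.ndarray, depth_range: tuple[int, int]) -> np.ndarray:
    """NaN-ignoring mean over a depth-pixel interval [z0, z1); all-NaN -> NaN."""
    z0, z1 = depth_range
    d = volume.shape[-1]
    if not (0 <= z0 < z1 <= d):
        raise ValueError(f"depth_range {depth_range} invalid for depth {d}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmean(volume[..., z0:z1], axis=-1)


def enface_orientation(
    theta_volume: np.ndarray,
    depth_range: tuple[int, int],
    bin_deg: float = 5.0,
) -> np.ndarray:
    """Histogram-peak axial orientation per lateral pixel.

    Valid (finite) orientation samples over the depth range are binned into
    [0, bin), [bin, 2*bin), ... [180-bin, 180); the output is the centre of
    the maximal bin, ties resolved toward the lowest bin index.  Pixels
    without any valid sample are NaN.
    """
    if bin_deg <= 0 or abs(180.0 / bin_deg - round(180.0 / bin_deg)) > 1e-9:
        raise ValueError(f"bin_deg={bin_deg} must divide 180")
    z0, z1 = depth_range
    d = theta_volume.shape[-1]
    if not (0 <= z0 < z1 <= d):
        raise ValueError(f"depth_range {depth_range} invalid for depth {d}")
    nbins = int(round(180.0 / bin_deg))
    sub = np.mod(theta_volume[..., z0:z1], 180.0)  # axial relabeling-safe
    valid = np.isfinite(sub)
    idx = np.zeros(sub.shape, dtype=np.int64)
    idx[valid] = np.minimum((sub[valid] / bin_deg).astype(np.int64), nbins - 1)
    counts = np.zeros(sub.shape[:-1] + (nbins,), dtype=np.int64)
    for k in range(nbins):
        counts[..., k] = ((idx == k) & valid).sum(axis=-1)
    peak = counts.argmax(axis=-1)  # first maximum = lowest bin on ties
    out = (peak + 0.5) * bin_deg
    return np.where(valid.any(axis=-1), out, np.nan)


def _ramp_weights(length: int, overlap_px: int) -> np.ndarray:
    """1-D blend weights: (d+1)/(O+1) where d is distance from the nearer
    edge, capped at 1; strictly positive so edge pixels remain defined."""
    d = np.minimum(np.arange(length), np.arange(length)[::-1])
    return np.minimum((d + 1.0) / (overlap_px + 1.0), 1.0)


def _blend_scalar(accum, wsum, tile_map, w, oy, ox):
    h, wdt = tile_map.shape
    finite = np.isfinite(tile_map)
    wa = np.where(finite, w, 0.0)
    accum[oy : oy + h, ox : ox + wdt] += wa * np.where(finite, tile_map, 0.0)
    wsum[oy : oy + h, ox : ox + wdt] += wa


def stitch(
    layout: TileLayout,
    refine_offsets: bool = False,
    max_shift_px: int = 5,
) -> ParameterMapStack:
    """Fuse tiles into a mosaic by linear blending.

    Scalar maps use normalized linear-ramp weights; the orientation map is
    blended as a weighted mean of doubled-angle unit vectors and halved back
    to [0, 180).  Masks are fused by weighted vote (>= 0.5).  Optional
    per-tile translation refinement by phase correlation against the mosaic
    accumulated so far (off by default; nominal offsets are trusted).
    """
    tiles = layout.tiles
    pixel_um = tiles[0][0].pixel_um

    offsets = [tuple(int(v) for v in off) for _, off in tiles]
    if refine_offsets and len(tiles) > 1:
        offsets = _refine_offsets(tiles, offsets, max_shift_px)

    ny = max(off[0] + t.shape[0] for (t, _), off in zip(tiles, offsets))
    nx = max(off[1] + t.shape[1] for (t, _), off in zip(tiles, offsets))

    mask_names = set()
    for t, _ in tiles:
        mask_names |= set(t.masks)
    have_refl = all(t.reflectivity_map is not None for t, _ in tiles)

    keys = ("mu_s", "ret", "cos2t", "sin2t") + (("refl",) if have_refl else ())
    acc = {k: np.zeros((ny, nx)) for k in keys}
    acc.update({f"mask:{k}": np.zeros((ny, nx)) for k in mask_names})
    wsum = {k: np.zeros((ny, nx)) for k in acc}

    for (tile, _), (oy, ox) in zip(tiles, offsets):
        h, w = tile.shape
        o_y = int(round(h * layout.overlap_frac))
        o_x = int(round(w * layout.overlap_frac))
        wt = np.outer(_ramp_weights(h, o_y), _ramp_weights(w, o_x))
        _blend_scalar(acc["mu_s"], wsum["mu_s"], tile.mu_s_map, wt, oy, ox)
        _blend_scalar(acc["ret"], wsum["ret"], tile.retardance_map, wt, oy, ox)
        if have_refl:
            _blend_scalar(acc["refl"], wsum["refl"], tile.reflectivity_map, wt, oy, ox)
        two_t = 2.0 * np.deg2rad(tile.orientation_map)
        _blend_scalar(acc["cos2t"], wsum["cos2t"], np.cos(two_t), wt, oy, ox)
        _blend_scalar(acc["sin2t"], wsum["sin2t"], np.sin(two_t), wt, oy, ox)
        for name in mask_names:
            m = tile.masks.get(name)
            if m is not None:
                _blend_scalar(
                    acc[f"mask:{name}"], wsum[f"mask:{name}"], m.astype(float), wt, oy, ox
                )

    def _norm(key):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = acc[key] / wsum[key]
        return np.where(wsum[key] > 0, out, np.nan)

    mu_s = _norm("mu_s")
    ret = _norm("ret")
    c2, s2 = _norm("cos2t"), _norm("sin2t")
    theta = np.mod(np.degrees(np.arctan2(s2, c2)), 360.0) / 2.0
    theta = np.mod(theta, 180.0)
    covered = np.isfinite(c2) & ((np.hypot(c2, s2)) > 1e-12)
    theta = np.where(covered, theta, np.nan)
    masks = {}
    for name in mask_names:
        v = _norm(f"mask:{name}")
        masks[name] = np.where(np.isfinite(v), v >= 0.5, False)
    return ParameterMapStack(
        mu_s_map=mu_s,
        retardance_map=ret,
        orientation_map=theta,
        pixel_um=pixel_um,
        masks=masks,
        reflectivity_map=_norm("refl") if have_refl else None,
    )


def blend_weights(layout: TileLayout) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-tile normalized blending weights on the mosaic grid.

    Returns (per-tile weight maps, coverage mask).  Wherever coverage is
    true the per-tile weights sum to exactly one; elsewhere they are zero.
    """
    tiles = layout.tiles
    offsets = [tuple(int(v) for v in off) for _, off in tiles]
    ny = max(off[0] + t.shape[0] for (t, _), off in zip(tiles, offsets))
    nx = max(off[1] + t.shape[1] for (t, _), off in zip(tiles, offsets))
    raw = []
    for (tile, _), (oy, ox) in zip(tiles, offsets):
        h, w = tile.shape
        o_y = int(round(h * layout.overlap_frac))
        o_x = int(round(w * layout.overlap_frac))
        wt = np.zeros((ny, nx))
        wt[oy : oy + h, ox : ox + w] = np.outer(
            _ramp_weights(h, o_y), _ramp_weights(w, o_x)
        )
        raw.append(wt)
    total = np.sum(raw, axis=0)
    covered = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = [np.where(covered, w / total, 0.0) for w in raw]
    return normed, covered


def _refine_offsets(tiles, offsets, max_shift_px):
    """Phase-correlation translation refinement against the first tile's frame."""
    from skimage.registration import phase_cross_correlation

    ref_tile, _ = tiles[0]
    refined = [offsets[0]]
    for (tile, _), (oy, ox) in zip(tiles[1:], offsets[1:]):
        # correlate on the nominal overlap region with the reference mosaic
        # frame; fall back to nominal offsets when the overlap is empty
        ref = np.nan_to_num(ref_tile.mu_s_map)
        mov = np.nan_to_num(tile.mu_s_map)
        ry0, ry1 = max(oy, 0), min(oy + mov.shape[0], ref.shape[0])
        rx0, rx1 = max(ox, 0), min(ox + mov.shape[1], ref.shape[1])
        if ry1 - ry0 < 8 or rx1 - rx0 < 8:
            refined.append((oy, ox))
            continue
        a = ref[ry0:ry1, rx0:rx1]
        b = mov[ry0 - oy : ry1 - oy, rx0 - ox : rx1 - ox]
        shift, _, _ = phase_cross_correlation(a, b, normalization=None)
        dy = int(np.clip(round(shift[0]), -max_shift_px, max_shift_px))
        dx = int(np.clip(round(shift[1]), -max_shift_px, max_shift_px))
        refined.append((max(oy + dy, 0), max(ox + dx, 0)))
    return refined


def stack_sections(
    sections: list[ParameterMapStack],
    slice_thickness_um: float,
) -> SectionVolume:
    """Concatenate serial sections along the cut axis (no registration needed
    for blockface acquisition: each section is imaged before it is cut)."""
    if not sections:
        raise ValueError("need at least one section")
    shapes = {s.shape for s in sections}
    if len(shapes) != 1:
        raise ValueError(f"sections must share one shape, got {shapes}")
    if len({s.pixel_um for s in sections}) != 1:
        raise ValueError("sections must share one pixel size")
    if slice_thickness_um <= 0:
        raise ValueError("slice_thickness_um must be positive")
    return SectionVolume(
        mu_s=np.stack([s.mu_s_map for s in sections]),
        retardance=np.stack([s.retardance_map for s in sections]),
        orientation=np.stack([s.orientation_map for s in sections]),
        pixel_um=sections[0].pixel_um,
        slice_thickness_um=slice_thickness_um,
    )
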
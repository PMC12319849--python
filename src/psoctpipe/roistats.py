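"""ROI-level comparison of PSOCT optical properties and diffusion metrics.

ROIs (0.9 x 0.9 mm by default) are placed on a regular lattice over the
white-matter mask; each ROI contributes NaN-ignoring means of mu_s,
retardance, ADC and FA, and axial circular means of the two orientation
sources.  Orientations are 180-degree periodic, so means use angle
doubling and differences use the half-circle (polar-space) metric:
the difference between 178 and 1 degrees is 3 degrees, not 177.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROI",
    "place_rois",
    "circ_mean_axial",
    "angular_difference",
    "pearson",
    "extract_roi_table",
    "wm_summary",
    "polar_histogram",
    "ROI_TABLE_COLUMNS",
]

ROI_TABLE_COLUMNS = [
    "roi_id",
    "center_x",
    "center_y",
    "mean_mu_s",
    "mean_retardance",
    "circ_mean_theta_psoct",
    "mean_adc",
    "fa",
    "circ_mean_theta_dmri",
    "n_valid_px",
]


@dataclass(frozen=True)
class ROI:
    """Square ROI box: top-left corner (y0, x0) and side length in pixels."""

    y0: int
    x0: int
    size: int

    @property
    def center_xy(self) -> tuple[float, float]:
        return (self.x0 + (self.size - 1) / 2.0, self.y0 + (self.size - 1) / 2.0)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.size), slice(self.x0, self.x0 + self.size))


def place_rois(
    wm_mask: np.ndarray,
    roi_size_um: float = 900.0,
    pixel_um: float = 10.0,
    n_rois: int | None = None,
    min_wm_frac: float = 0.8,
    seed: int | None = None,
) -> list[ROI]:
    """Evenly distributed ROI boxes inside the white matter.

    Candidate boxes tile a regular lattice with stride = ROI side; boxes
    whose white-matter fraction falls below ``min_wm_frac`` are dropped.  If
    more than ``n_rois`` candidates survive they are subsampled with a
    deterministic even stride; the seed only breaks stride rounding ties.
    """
    size = max(1, int(round(roi_size_um / pixel_um)))
    ny, nx = wm_mask.shape
    if size > min(ny, nx):
        raise ValueError("ROI size exceeds map extent")
    boxes = []
    for y0 in range(0, ny - size + 1, size):
        for x0 in range(0, nx - size + 1, size):
            frac = wm_mask[y0 : y0 + size, x0 : x0 + size].mean()
            if frac >= min_wm_frac:
                boxes.append(ROI(y0=y0, x0=x0, size=size))
    if not boxes:
        raise ValueError(
            f"no candidate ROI reaches white-matter fraction {min_wm_frac}"
        )
    if n_rois is not None and len(boxes) > n_rois:
        pos = np.linspace(0, len(boxes) - 1, n_rois)
        rng = np.random.default_rng(seed)
        idx = []
        for p in pos:
            lo, hi = int(np.floor(p)), int(np.ceil(p))
            if lo == hi or abs(p - lo) != abs(p - hi):
                idx.append(int(round(p)))
            else:  # exact .5 tie: seed decides
                idx.append(int(rng.choice([lo, hi])))
        idx = sorted(set(idx))
        k = 0
        while len(idx) < n_rois:  # backfill collisions deterministically
            if k not in idx:
                idx.append(k)
            k += 1
        boxes = [boxes[i] for i in sorted(idx)[:n_rois]]
    return boxes


def circ_mean_axial(
    angles_deg: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Axial circular mean: double the angles, average unit vectors, halve.

    Input angles are degrees in [0, 180); NaNs are ignored.  A mean
    resultant vector shorter than 1e-9 (perfectly balanced input, e.g.
    {0, 90}) has no defined mean and returns NaN.
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != a.shape:
            raise ValueError("weights must match angles in length")
    keep = np.isfinite(a) & np.isfinite(w)
    a, w = a[keep], w[keep]
    if a.size == 0:
        raise ValueError("need at least one finite angle")
    doubled = 2.0 * np.deg2rad(a)
    c = float(np.sum(w * np.cos(doubled)))
    s = float(np.sum(w * np.sin(doubled)))
    wt = float(np.sum(w))
    if wt <= 0 or np.hypot(c, s) / wt < 1e-9:
        return np.nan
    return float(np.mod(np.degrees(np.arctan2(s, c)), 360.0) / 2.0) % 180.0


def angular_difference(a, b):
    """Axial angular difference on the half circle, degrees in [0, 90].

    The difference minimizes over the 180-degree ambiguity, so
    angular_difference(178, 1) == 3, not 177.  NaN inputs propagate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.abs(a - b) % 180.0
    out = np.minimum(d, 180.0 - d)
    if out.ndim == 0:
        return float(out)
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation with pairwise NaN deletion."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def _nanmean(arr) -> float:
    vals = arr[np.isfinite(arr)]
    return float(vals.mean()) if vals.size else np.nan


def extract_roi_table(
    psoct,
    dmri_maps: dict[str, np.ndarray],
    rois: list[ROI],
) -> pd.DataFrame:
    """Per-ROI means and circular means on a common (PSOCT) grid.

    ``psoct`` is a ParameterMapStack; ``dmri_maps`` holds 'adc', 'fa' and
    'theta' maps already resampled / reoriented onto the same grid.  ROIs
    with no valid PSOCT pixel are dropped with a warning.
    """
    import warnings

    shapes = {psoct.shape} | {m.shape for m in dmri_maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"all maps must share the PSOCT grid, got {shapes}")
    rows = []
    for i, roi in enumerate(rois):
        sl = roi.slices()
        mu = psoct.mu_s_map[sl]
        n_valid = int(np.isfinite(mu).sum())
        if n_valid == 0:
            warnings.warn(f"ROI {i} has no valid pixels; dropped")
            continue
        theta_p = psoct.orientation_map[sl]
        theta_d = dmri_maps["theta"][sl]
        cx, cy = roi.center_xy
        rows.append(
            {
                "roi_id": i,
                "center_x": cx,
                "center_y": cy,
                "mean_mu_s": _nanmean(mu),
                "mean_retardance": _nanmean(psoct.retardance_map[sl]),
                "circ_mean_theta_psoct": (
                    circ_mean_axial(theta_p) if np.isfinite(theta_p).any() else np.nan
                ),
                "mean_adc": _nanmean(dmri_maps["adc"][sl]),
                "fa": _nanmean(dmri_maps["fa"][sl]),
                "circ_mean_theta_dmri": (
                    circ_mean_axial(theta_d) if np.isfinite(theta_d).any() else np.nan
                ),
                "n_valid_px": n_valid,
            }
        )
    return pd.DataFrame(rows, columns=ROI_TABLE_COLUMNS)


def wm_summary(
    map_2d: np.ndarray, wm_mask: np.ndarray, ddof: int = 0
) -> tuple[float, float]:
    """NaN-ignoring (mean, sd) over white-matter pixels; population sd default."""
    if not np.asarray(wm_mask, dtype=bool).any():
        raise ValueError("white-matter mask is empty")
    vals = np.asarray(map_2d, dtype=float)[np.asarray(wm_mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values under the mask")
    return float(vals.mean()), float(vals.std(ddof=ddof))


def polar_histogram(
    differences_deg: np.ndarray,
    bin_deg: float = 10.0,
    plot_path: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of axial angular differences over [0, 90].

    Returns (counts, bin_edges); counts sum to the number of finite inputs.
    If ``plot_path`` is given, a polar wedge plot is written there.
    """
    if bin_deg <= 0 or abs(90.0 / bin_deg - round(90.0 / bin_deg)) > 1e-9:
        raise ValueError(f"bin_deg={bin_deg} must divide 90")
    d = np.asarray(differences_deg, dtype=float).ravel()
    d = d[np.isfinite(d)]
    if d.size and (d.min() < 0 or d.max() > 90):
        raise ValueError("differences must lie in [0, 90]")
    nbins = int(round(90.0 / bin_deg))
    edges = np.linspace(0.0, 90.0, nbins + 1)
    idx = np.minimum((d / bin_deg).astype(int), nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
        centers = np.deg2rad(edges[:-1] + bin_deg / 2.0)
        ax.bar(centers, counts, width=np.deg2rad(bin_deg), alpha=0.75)
        ax.set_thetamin(0)
        ax.set_thetamax(90)
        ax.set_title("PSOCT vs dMRI axial angular difference")
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return counts, edges
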
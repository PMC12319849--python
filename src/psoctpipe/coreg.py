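"""Cross-modal affine registration and orientation-vector reorientation.

The diffusion ADC map is registered to the PSOCT scattering-coefficient map
(the pair with the best gray/white matter contrast) by maximizing the
normalized cross-correlation over affine parameters, coarse to fine, with a
center-of-mass and pixel-size-ratio initialization.  Because ADC and mu_s
contrast are anti-correlated in white matter, the moving map is negated
before matching.  Registration quality is evaluated with Dice overlap of
tissue / white-matter masks; diffusion orientation vectors are carried into
the PSOCT plane by the rotational component (polar decomposition) of the
recovered affine and projected in-plane.

Conventions: transforms act on (x, y) pixel-center coordinates (0-based,
x = column, y = row):  p_fixed = matrix @ p_moving + translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.linalg import polar
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.transform import rescale

__all__ = [
    "AffineTransform",
    "register_affine",
    "resample",
    "dice",
    "reorient_and_project",
    "make_masks",
    "otsu_threshold",
]


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's between-class-variance-maximizing threshold on finite values."""
    finite = np.asarray(values, dtype=float)
    finite = finite[np.isfinite(finite)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise ValueError("degenerate input: no histogram to threshold")
    return float(threshold_otsu(finite))


@dataclass
class AffineTransform:
    """Affine map from moving-grid to fixed-grid pixel coordinates."""

    matrix: np.ndarray
    translation: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if not np.isfinite(self.matrix).all() or not np.isfinite(self.translation).all():
            raise ValueError("transform entries must be finite")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("linear part must be invertible")

    @property
    def rotational_component(self) -> np.ndarray:
        """Rotation factor of the polar decomposition of the linear part."""
        u, _ = polar(self.matrix, side="right")
        if np.linalg.det(u) < 0:  # reflection: fold into the symmetric factor
            u = u @ np.diag([1.0, -1.0])
        return u

    @property
    def rotation_deg(self) -> float:
        """In-plane rotation angle (degrees, CCW about +z in x-y coords)."""
        u = self.rotational_component
        return float(np.degrees(np.arctan2(u[1, 0], u[0, 0])))

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(matrix=inv, translation=-inv @ self.translation)

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        return pts @ self.matrix.T + self.translation

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "convention": "p_fixed = matrix @ p_moving + translation; "
            "(x, y) 0-based pixel centers",
            **{k: v for k, v in self.meta.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        meta = {k: v for k, v in d.items() if k not in ("matrix", "translation", "convention")}
        return cls(matrix=np.array(d["matrix"]), translation=np.array(d["translation"]), meta=meta)


def resample(
    arr: np.ndarray,
    transform: AffineTransform,
    out_shape: tuple[int, int],
    interpolation: str = "linear",
) -> np.ndarray:
    """Pull-back resampling of a moving-grid map onto the fixed grid.

    out[q] = arr(matrix^-1 (q - t)); out-of-domain pixels are NaN (linear)
    or 0/False (nearest, used for binary masks).
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    inv = np.linalg.inv(transform.matrix)
    # (x,y) -> (row,col) conjugation for scipy.ndimage
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    mat_rc = swap @ inv @ swap
    off_rc = -swap @ inv @ transform.translation
    is_bool = arr.dtype == bool
    work = arr.astype(float)
    cval = 0.0 if (order == 0 or is_bool) else np.nan
    out = ndimage.affine_transform(
        work, mat_rc, offset=off_rc, output_shape=out_shape, order=order, cval=cval
    )
    if is_bool:
        return out > 0.5
    return out


def _center_of_mass(img: np.ndarray) -> np.ndarray:
    w = img - np.nanmin(img)
    w = np.nan_to_num(w)
    total = w.sum()
    if total == 0:
        return np.array([(img.shape[1] - 1) / 2.0, (img.shape[0] - 1) / 2.0])
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return np.array([(w * xx).sum() / total, (w * yy).sum() / total])


def _params_to_transform(params, s0, t0):
    rot, lsx, lsy, shear, dtx, dty = params
    r = np.deg2rad(rot)
    rot_m = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
    scale_m = np.diag([s0 * np.exp(lsx), s0 * np.exp(lsy)])
    shear_m = np.array([[1.0, shear], [0.0, 1.0]])
    a = rot_m @ scale_m @ shear_m
    return a, t0 + np.array([dtx, dty])


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() < 16:
        return -1.0
    x = a[valid] - a[valid].mean()
    y = b[valid] - b[valid].mean()
    nx, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny_ == 0:
        return -1.0
    return float((x @ y) / (nx * ny_))


def register_affine(
    fixed: np.ndarray,
    moving: np.ndarray,
    moving_pixel_um: float,
    fixed_pixel_um: float,
    levels: int = 3,
    invert_moving: bool = True,
) -> AffineTransform:
    """Affine registration of a moving (ADC-like) map onto a fixed (mu_s) map.

    Maximizes NCC of the negated moving map (ADC and mu_s contrast are
    anti-correlated) coarse-to-fine over ``levels`` pyramid levels,
    initialized by the pixel-size ratio and center-of-mass alignment.
    Returns the transform mapping moving pixel coordinates to fixed pixel
    coordinates.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    for name, img in (("fixed", fixed), ("moving", moving)):
        if not np.isfinite(img).all():
            raise ValueError(f"{name} map contains non-finite values")
        if np.unique(img).size < 2:
            raise ValueError(f"{name} map is constant; cannot register")
    mov = -moving if invert_moving else moving
    s0 = moving_pixel_um / fixed_pixel_um
    t0 = _center_of_mass(fixed) - s0 * _center_of_mass(mov)

    params = np.zeros(6)
    factors = [2 ** (levels - 1 - i) for i in range(levels)]
    for factor in factors:
        if factor > 1:
            fixed_l = rescale(
                fixed, 1.0 / factor, anti_aliasing=True, preserve_range=True
            )
        else:
            fixed_l = fixed

        def objective(p, _factor=factor, _fixed_l=fixed_l):
            a, t = _params_to_transform(p, s0, t0)
            tr = AffineTransform(matrix=a / _factor, translation=t / _factor)
            warped = resample(mov, tr, _fixed_l.shape, interpolation="linear")
            return -_ncc(_fixed_l, warped)

        step = np.diag([2.0, 0.05, 0.05, 0.05, 4.0 * factor, 4.0 * factor])
        res = optimize.minimize(
            objective,
            params,
            method="Powell",
            options={"direc": step, "xtol": 1e-4, "ftol": 1e-7, "maxiter": 60},
        )
        params = res.x
    a, t = _params_to_transform(params, s0, t0)
    return AffineTransform(
        matrix=a,
        translation=t,
        meta={
            "moving_pixel_um": moving_pixel_um,
            "fixed_pixel_um": fixed_pixel_um,
            "ncc": -float(res.fun),
        },
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks -> 1 by convention."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def reorient_and_project(
    vectors: np.ndarray,
    transform: AffineTransform,
    valid: np.ndarray | None = None,
    min_inplane: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate diffusion unit vectors into the PSOCT frame; in-plane angles.

    Applies the rotational component of the affine (as an in-plane rotation
    about +z) to (x, y, z) unit vectors, projects onto the imaging plane,
    and returns axial angles in [0, 180) plus validity flags.  Vectors whose
    projected magnitude falls below ``min_inplane`` are through-plane and
    flagged invalid (angle NaN).
    """
    v = np.asarray(vectors, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("vectors must have a trailing dimension of 3")
    u = transform.rotational_component
    r3 = np.eye(3)
    r3[:2, :2] = u
    vp = v @ r3.T
    mag = np.hypot(vp[..., 0], vp[..., 1])
    angles = np.mod(np.degrees(np.arctan2(vp[..., 1], vp[..., 0])), 180.0)
    ok = mag >= min_inplane
    if valid is not None:
        ok = ok & np.asarray(valid, dtype=bool)
    return np.where(ok, angles, np.nan), ok


def _clean_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest connected component and fill holes."""
    lab = label(mask)
    if lab.max() == 0:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    keep = lab == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(keep)


def make_masks(
    map_2d: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
    invert: bool = False,
    wm_map: np.ndarray | None = None,
    wm_value: float | None = None,
) -> dict[str, np.ndarray]:
    """Tissue and white-matter masks from parameter maps.

    Tissue = foreground by Otsu (or the fixed ``value`` with
    method="threshold") on ``map_2d``, then largest-component retention and
    hole filling.  ``invert=True`` negates the map first — use it for maps
    where tissue is dark (e.g. ADC, where tissue diffusivity is below free
    water).  WM = a second threshold (``wm_value`` or Otsu within the
    tissue mask) applied to ``wm_map`` if given (e.g. FA for diffusion
    data, mu_s for PSOCT), else to the tissue map itself.
    """
    img = np.asarray(map_2d, dtype=float)
    if invert:
        img = -img
    finite = img[np.isfinite(img)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise ValueError("degenerate map: no histogram to threshold")
    if method == "otsu":
        thr = otsu_threshold(finite)
    elif method == "threshold":
        if value is None:
            raise ValueError("method='threshold' requires a value")
        thr = float(value) * (-1.0 if invert else 1.0)
    else:
        raise ValueError(f"unknown mask method {method!r}")
    tissue = _clean_mask(np.isfinite(img) & (img >= thr))
    if not tissue.any():
        raise ValueError("tissue mask is empty")
    src = img if wm_map is None else np.asarray(wm_map, dtype=float)
    if src.shape != img.shape:
        raise ValueError("wm_map must match map_2d in shape")
    inside = src[tissue & np.isfinite(src)]
    if wm_value is not None:
        wm_thr = float(wm_value)
    elif inside.size == 0 or np.ptp(inside) == 0:
        wm_thr = np.inf  # flat foreground: no WM/GM contrast
    else:
        wm_thr = otsu_threshold(inside)
    wm = tissue & np.isfinite(src) & (src >= wm_thr)
    return {"tissue": tissue, "wm": wm}
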
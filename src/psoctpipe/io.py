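"""Readers and writers for maps, volumes, streamlines and provenance.

Maps and volumes go to 32-bit float multi-page TIFF (with a JSON sidecar
carrying pixel sizes and conventions) or NIfTI-1 (pixel sizes in the pixdim
fields, mm).  Streamlines are always written as newline-delimited JSON (one
streamline per line) and, additionally, as TrackVis .trk.  Orientation maps
are stored in degrees, [0, 180), float32, NaN for invalid — the single
convention used repo-wide.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "write_map",
    "read_map",
    "write_orientation_preview",
    "write_streamlines_ndjson",
    "read_streamlines_ndjson",
    "write_streamlines_trk",
    "read_streamlines_trk",
    "write_json",
    "read_json",
]

_TIFF_EXT = {".tif", ".tiff"}
_NIFTI_EXT = {".nii", ".nii.gz"}


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def write_map(
    path: str | Path,
    arr: np.ndarray,
    pixel_um: float,
    axial_pixel_um: float | None = None,
    meta: dict | None = None,
) -> Path:
    """Write a 2-D map or 3-D volume; format chosen by extension.

    TIFF stores float32 pages plus a ``<name>.json`` sidecar; NIfTI stores
    pixel sizes in mm in the header pixdim.  For 3-D arrays the leading axis
    is the page/section axis and ``axial_pixel_um`` its spacing.
    """
    path = Path(path)
    arr = np.asarray(arr)
    data = arr.astype(np.float32)
    meta_all = {
        "pixel_um": float(pixel_um),
        "axial_pixel_um": None if axial_pixel_um is None else float(axial_pixel_um),
        "orientation_convention": "degrees in [0,180), NaN invalid",
        **(meta or {}),
    }
    ext = _suffix(path)
    if ext in _TIFF_EXT:
        tifffile.imwrite(path, data, photometric="minisblack")
        Path(str(path) + ".json").write_text(json.dumps(meta_all, indent=1))
    elif ext in _NIFTI_EXT:
        mm = pixel_um / 1000.0
        zooms = [mm, mm] if data.ndim == 2 else [
            (axial_pixel_um or pixel_um) / 1000.0,
            mm,
            mm,
        ]
        affine = np.eye(4)
        for i, z in enumerate(zooms):
            affine[i, i] = z
        img = nib.Nifti1Image(data, affine=affine)
        img.header.set_zooms(tuple(zooms))
        img.header["descrip"] = b"psoctpipe map"
        nib.save(img, path)
        Path(str(path) + ".json").write_text(json.dumps(meta_all, indent=1))
    else:
        raise ValueError(f"unsupported map format {ext!r} (use TIFF or NIfTI)")
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a map/volume written by :func:`write_map`; returns (array, meta)."""
    path = Path(path)
    ext = _suffix(path)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if ext in _TIFF_EXT:
        return tifffile.imread(path), meta
    if ext in _NIFTI_EXT:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float32)
        zooms = img.header.get_zooms()
        meta.setdefault("pixel_um", float(zooms[-1]) * 1000.0)
        return data, meta
    raise ValueError(f"unsupported map format {ext!r}")


def write_orientation_preview(
    path: str | Path,
    orientation_map: np.ndarray,
    brightness: np.ndarray | None = None,
) -> Path:
    """8-bit HSV-encoded orientation preview PNG (hue = 2*theta convention).

    Hue encodes the axial angle (full hue circle per 180 degrees, so 0 and
    180 share a color); value encodes ``brightness`` (e.g. retardance)
    normalized to its finite range, or validity alone.  NaN pixels are black.
    """
    from matplotlib.colors import hsv_to_rgb
    from PIL import Image

    theta = np.asarray(orientation_map, dtype=float)
    valid = np.isfinite(theta)
    hue = np.where(valid, np.mod(theta, 180.0) / 180.0, 0.0)
    if brightness is None:
        val = valid.astype(float)
    else:
        b = np.asarray(brightness, dtype=float)
        finite = b[np.isfinite(b)]
        span = np.ptp(finite) if finite.size else 0.0
        val = (b - (finite.min() if finite.size else 0.0)) / span if span else valid
        val = np.clip(np.nan_to_num(val), 0.0, 1.0) * valid
    hsv = np.stack([hue, np.ones_like(hue), val], axis=-1)
    rgb = (hsv_to_rgb(hsv) * 255).astype(np.uint8)
    Image.fromarray(rgb).save(path)
    return Path(path)


# ---------------------------------------------------------------------------
# streamlines
# ---------------------------------------------------------------------------


def write_streamlines_ndjson(path: str | Path, streamlines, pixel_um: float) -> Path:
    """One JSON object per line: {"points": [[x, y], ...], "length_px": L}."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"format": "psoctpipe-streamlines", "pixel_um": pixel_um}))
        fh.write("\n")
        for s in streamlines:
            rec = {
                "points": np.asarray(s.points, dtype=float).round(4).tolist(),
                "length_px": float(s.length_px),
            }
            fh.write(json.dumps(rec))
            fh.write("\n")
    return path


def read_streamlines_ndjson(path: str | Path):
    from .tract2d import Streamline

    lines = Path(path).read_text().strip().splitlines()
    header = json.loads(lines[0])
    out = []
    for line in lines[1:]:
        rec = json.loads(line)
        out.append(
            Streamline(points=np.asarray(rec["points"]), length_px=rec["length_px"])
        )
    return out, header


def write_streamlines_trk(
    path: str | Path, streamlines, pixel_um: float, shape_yx: tuple[int, int]
) -> Path:
    """TrackVis .trk export; 2-D tracks get z = 0 (plane of the section)."""
    from nibabel.streamlines import Tractogram, save as trk_save
    from nibabel.streamlines.trk import TrkFile

    mm = pixel_um / 1000.0
    sl3d = [
        np.column_stack(
            [s.points[:, 0] * mm, s.points[:, 1] * mm, np.zeros(len(s.points))]
        ).astype(np.float32)
        for s in streamlines
    ]
    tractogram = Tractogram(sl3d, affine_to_rasmm=np.eye(4))
    header = {
        "voxel_sizes": (mm, mm, 1.0),
        "dimensions": (shape_yx[1], shape_yx[0], 1),
        "voxel_order": "RAS",
    }
    trk_save(TrkFile(tractogram, header=header), str(path))
    return Path(path)


def read_streamlines_trk(path: str | Path):
    from nibabel.streamlines import load as trk_load

    trk = trk_load(str(path))
    return list(trk.streamlines)


# ---------------------------------------------------------------------------
# small JSON helpers (reports, transforms, provenance)
# ---------------------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(payload), indent=1, sort_keys=True))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
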
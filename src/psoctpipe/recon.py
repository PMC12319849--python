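"""PSOCT reconstruction: depth profiles to reflectivity, retardance, axis, mu_s.

Given dual-channel complex depth profiles A1 e^{i phi1}, A2 e^{i phi2}, the
per-pixel estimators are

    R(z)     = A1(z)^2 + A2(z)^2                 (proportionality constant 1)
    delta(z) = arctan(A1(z) / A2(z))             in [0, 90] degrees
    theta(z) = wrap(phi1(z) - phi2(z)) / 2       in [0, 180) degrees

and the depth-resolved scattering coefficient follows the tail-normalized
intensity estimator

    mu_s(z) = I(z) / (2 * dz * sum_{j=z+1..d} I(j)),

with I the linear reflectivity signal, dz the axial pixel size in mm and d
the total imaging depth in pixels.  The finite tail sum is implemented
exactly as printed; the estimator is biased upward near the end of the
depth range (the tail integral is truncated), which an optional tail
truncation parameter can trim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import ComplexAScanVolume

__all__ = [
    "ReconVolume",
    "fourier_reconstruct",
    "compute_reflectivity",
    "compute_retardance",
    "compute_axis",
    "compute_scattering_profile",
    "reconstruct_volume",
]


@dataclass
class ReconVolume:
    """Per-voxel reconstructed quantities; depth is the last axis.

    reflectivity: linear-scale R, arbitrary units.  retardance_deg in
    [0, 90] or NaN; axis_deg in [0, 180) or NaN; mu_s in mm^-1 (NaN at the
    last pixel and wherever the tail sum vanishes).
    """

    reflectivity: np.ndarray
    retardance_deg: np.ndarray
    axis_deg: np.ndarray
    mu_s: np.ndarray
    axial_pixel_um: float
    depth_px: int
    metadata: dict = field(default_factory=dict)


def fourier_reconstruct(
    spectra_ch1: np.ndarray,
    spectra_ch2: np.ndarray,
    axial_pixel_um: float,
) -> ComplexAScanVolume:
    """Complex depth profiles from real spectral interference fringes.

    Per channel: remove DC by mean subtraction along the spectral axis
    (last), apply the inverse DFT, and keep the positive-frequency half;
    output depth length is floor(n_spectral / 2).
    """
    s1 = np.asarray(spectra_ch1, dtype=float)
    s2 = np.asarray(spectra_ch2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"channel spectra shapes differ: {s1.shape} vs {s2.shape}")
    n = s1.shape[-1]
    if n < 2:
        raise ValueError("spectra must have length >= 2")
    half = n // 2

    def _one(s):
        prof = np.fft.ifft(s - s.mean(axis=-1, keepdims=True), axis=-1)
        return prof[..., :half]

    return ComplexAScanVolume(
        ch1=_one(s1), ch2=_one(s2), axial_pixel_um=axial_pixel_um
    )


def compute_reflectivity(ascan: ComplexAScanVolume) -> np.ndarray:
    """R(z) = A1(z)^2 + A2(z)^2, linear scale."""
    return np.abs(ascan.ch1) ** 2 + np.abs(ascan.ch2) ** 2


def compute_retardance(ascan: ComplexAScanVolume) -> np.ndarray:
    """Cumulative retardance arctan(A1/A2) in degrees, [0, 90]; NaN if both zero."""
    a1 = np.abs(ascan.ch1)
    a2 = np.abs(ascan.ch2)
    delta = np.degrees(np.arctan2(a1, a2))
    return np.where((a1 == 0) & (a2 == 0), np.nan, delta)


def compute_axis(
    ascan: ComplexAScanVolume,
    snr_floor: float | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Optic-axis orientation (phi1 - phi2)/2 in degrees, [0, 180).

    The phase difference is wrapped into [0, 360) before halving, so the
    result is the axial (180-degree-periodic) orientation.  Pixels whose
    cross-polarized amplitude A1 does not exceed the SNR floor return NaN —
    the axis is meaningless without cross-polarized signal.  The floor
    defaults to 3 * noise_sd when the noise level is known, else 0.
    """
    if snr_floor is None:
        snr_floor = 3.0 * noise_sd if noise_sd is not None else 0.0
    a1 = np.abs(ascan.ch1)
    dphi = np.degrees(np.angle(ascan.ch1) - np.angle(ascan.ch2))
    theta = np.mod(dphi, 360.0) / 2.0
    theta = np.mod(theta, 180.0)  # guard the 360.0-epsilon edge case
    return np.where(a1 > snr_floor, theta, np.nan)


def compute_scattering_profile(
    intensity: np.ndarray,
    delta_mm: float,
    tail_truncate_px: int = 0,
) -> np.ndarray:
    """Depth-resolved scattering coefficient (mm^-1) from the intensity tail.

    mu_s(z) = I(z) / (2 * delta_mm * sum_{j=z+1..d} I(j)) along the last
    axis.  The last pixel (empty tail) and any pixel with a zero tail sum
    are NaN.  ``tail_truncate_px`` drops that many trailing pixels before
    the computation (output keeps full length, padded with NaN).
    """
    intensity = np.asarray(intensity, dtype=float)
    if delta_mm <= 0:
        raise ValueError("delta_mm must be positive")
    d = intensity.shape[-1]
    if d < 2:
        raise ValueError("need at least 2 depth pixels")
    if (intensity < 0).any():
        raise ValueError("intensity must be non-negative")
    if not 0 <= tail_truncate_px < d:
        raise ValueError("tail_truncate_px must be in [0, depth)")
    work = intensity[..., : d - tail_truncate_px] if tail_truncate_px else intensity
    # exclusive reverse cumulative sum: tail[z] = sum_{j>z} I(j)
    rev = np.cumsum(work[..., ::-1], axis=-1)[..., ::-1]
    tail = rev - work
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = work / (2.0 * delta_mm * tail)
    mu = np.where(tail > 0, mu, np.nan)
    if tail_truncate_px:
        pad = np.full(intensity.shape[:-1] + (tail_truncate_px,), np.nan)
        mu = np.concatenate([mu, pad], axis=-1)
    return mu


def reconstruct_volume(
    ascan: ComplexAScanVolume,
    snr_floor: float | None = None,
    noise_sd: float | None = None,
    tail_truncate_px: int = 0,
) -> ReconVolume:
    """All four per-pixel quantities for a volume (or single A-line)."""
    if noise_sd is None:
        noise_sd = ascan.metadata.get("noise_sd")
    refl = compute_reflectivity(ascan)
    delta = compute_retardance(ascan)
    theta = compute_axis(ascan, snr_floor=snr_floor, noise_sd=noise_sd)
    mu_s = compute_scattering_profile(
        refl, ascan.axial_pixel_um / 1000.0, tail_truncate_px=tail_truncate_px
    )
    return ReconVolume(
        reflectivity=refl,
        retardance_deg=delta,
        axis_deg=theta,
        mu_s=mu_s,
        axial_pixel_um=ascan.axial_pixel_um,
        depth_px=ascan.depth_px,
        metadata=dict(ascan.metadata),
    )
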
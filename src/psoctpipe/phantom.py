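"""Synthetic birefringent fiber phantoms and matched coarse diffusion maps.

The phantom stands in for postmortem tissue blocks: every downstream stage
(reconstruction, en-face mapping, tractography, co-registration, ROI
statistics) can be exercised against known ground truth.

Forward model
-------------
Light propagates along +z through a stack of thin birefringent layers.
Backscattered amplitude from depth pixel ``z`` follows single-scattering
exponential decay,

    A(z) = sqrt(beta * mu_s(z)) * exp(-sum_{j<=z} mu_s(j) * dz),

with ``beta`` a fixed backscatter fraction.  Polarization is propagated with
per-pixel linear-retarder Jones matrices J_k = R(theta_k) D(delta_k)
R(-theta_k), delta_k = (2*pi/lambda) * dn_k * dz.  The round trip uses the
transpose product M(z) = J(z)^T J(z), which is itself a linear retarder; its
retardance Gamma(z) is the cumulative double-pass retardation and its axis
theta_a(z) the apparent optic axis.  The (idealized) dual-channel detector
reports

    ch1 = A |sin Gamma| exp(i * 2 * theta_a),   ch2 = A |cos Gamma|,

so that for a uniform-axis medium arctan(A1/A2) equals the wrapped
double-pass retardation and (phi1 - phi2)/2 equals the true axis.
Independent complex Gaussian noise (per-quadrature standard deviation
``noise_sd``) is added to each channel, channel 1 first, depth-major.

Conventions: volumes are arrays of shape (ny, nx, nz); in-plane angles are
degrees in [0, 180) measured counterclockwise from +x; mu_s is mm^-1; pixel
sizes are stored in micrometres and converted to mm at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Box",
    "Cylinder",
    "Region",
    "PhantomSpec",
    "ComplexAScanVolume",
    "GroundTruth",
    "DmriMaps",
    "simulate_ascan",
    "simulate_volume",
    "simulate_tiled_acquisition",
    "simulate_dmri_maps",
    "demo_phantom_spec",
    "developmental_series",
]

DEFAULT_BACKSCATTER_FRACTION = 0.01


# ---------------------------------------------------------------------------
# geometry and spec containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in voxel coordinates, half-open [lo, hi) per axis."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def slices(self, shape_yxz: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        ny, nx, nz = shape_yxz
        x0, x1 = np.clip(self.x, 0, nx)
        y0, y1 = np.clip(self.y, 0, ny)
        z0, z1 = np.clip(self.z, 0, nz)
        return (slice(y0, y1), slice(x0, x1), slice(z0, z1))

    def mask(self, shape_yxz: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape_yxz, dtype=bool)
        m[self.slices(shape_yxz)] = True
        return m


@dataclass(frozen=True)
class Cylinder:
    """Oriented cylinder given by two endpoints (x, y, z) and a radius, voxels."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def mask(self, shape_yxz: tuple[int, int, int]) -> np.ndarray:
        ny, nx, nz = shape_yxz
        yy, xx, zz = np.meshgrid(
            np.arange(ny), np.arange(nx), np.arange(nz), indexing="ij"
        )
        p = np.stack([xx, yy, zz], axis=-1).astype(float)
        a = np.asarray(self.p0, dtype=float)
        b = np.asarray(self.p1, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d2 = ((p - a) ** 2).sum(-1)
            return d2 <= self.radius**2
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d2 = ((p - closest) ** 2).sum(-1)
        return d2 <= self.radius**2


@dataclass(frozen=True)
class Region:
    """One homogeneous fiber population (or isotropic block) of the phantom.

    ``axis_deg`` is the in-plane fiber axis in [0, 180); ``through_plane_deg``
    the inclination out of the imaging plane in [-90, 90].  Apparent
    birefringence is scaled by cos^2(inclination), the standard projection
    effect, so steeply inclined fibers appear nearly non-birefringent.
    """

    geometry: Box | Cylinder
    mu_s: float
    birefringence: float = 0.0
    axis_deg: float = 0.0
    through_plane_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if self.birefringence < 0:
            raise ValueError(f"birefringence must be >= 0, got {self.birefringence}")
        if not 0.0 <= self.axis_deg < 180.0:
            raise ValueError(f"axis_deg must be in [0, 180), got {self.axis_deg}")
        if not -90.0 <= self.through_plane_deg <= 90.0:
            raise ValueError("through_plane_deg must be in [-90, 90]")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic tissue block.

    grid_shape is (nx, ny, nz); arrays produced from the spec are indexed
    [y, x, z].  Uncovered voxels are background: ``background_mu_s`` and zero
    birefringence.  Later regions override earlier ones where they overlap.
    """

    grid_shape: tuple[int, int, int]
    lateral_pixel_um: float = 10.0
    axial_pixel_um: float = 4.2
    wavelength_um: float = 1.3
    regions: tuple[Region, ...] = ()
    background_mu_s: float = 1.0
    backscatter_fraction: float = DEFAULT_BACKSCATTER_FRACTION

    def __post_init__(self) -> None:
        if any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape entries must all be >= 1")
        if min(self.lateral_pixel_um, self.axial_pixel_um, self.wavelength_um) <= 0:
            raise ValueError("pixel sizes and wavelength must be positive")
        if self.background_mu_s < 0:
            raise ValueError("background_mu_s must be >= 0")
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def shape_yxz(self) -> tuple[int, int, int]:
        nx, ny, nz = self.grid_shape
        return (ny, nx, nz)


@dataclass
class ComplexAScanVolume:
    """Dual-channel complex depth profiles; depth is the last axis."""

    ch1: np.ndarray
    ch2: np.ndarray
    axial_pixel_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=complex)
        self.ch2 = np.asarray(self.ch2, dtype=complex)
        if self.ch1.shape != self.ch2.shape:
            raise ValueError(
                f"channel shapes differ: {self.ch1.shape} vs {self.ch2.shape}"
            )
        if self.axial_pixel_um <= 0:
            raise ValueError("axial_pixel_um must be positive")
        if not (np.isfinite(self.ch1).all() and np.isfinite(self.ch2).all()):
            raise ValueError("raw channels must be finite everywhere")

    @property
    def depth_px(self) -> int:
        return self.ch1.shape[-1]


@dataclass
class GroundTruth:
    """Voxel-wise truth maps for recovery tests, shape (ny, nx, nz)."""

    mu_s: np.ndarray
    birefringence: np.ndarray  # intrinsic dn
    birefringence_apparent: np.ndarray  # dn * cos^2(inclination)
    axis_deg: np.ndarray
    through_plane_deg: np.ndarray
    lateral_pixel_um: float
    axial_pixel_um: float
    wavelength_um: float

    def fiber_mask(self) -> np.ndarray:
        return self.birefringence > 0


@dataclass
class DmriMaps:
    """Coarse-grid diffusion stand-in: ADC, FA, principal direction.

    ``principal_dir`` holds unit (x, y, z) vectors; ``valid`` flags voxels
    with a meaningful direction (anisotropy above threshold).
    """

    adc: np.ndarray
    fa: np.ndarray
    principal_dir: np.ndarray
    valid: np.ndarray
    grid_spacing_mm: float = 0.8

    def __post_init__(self) -> None:
        fa_ok = self.fa[np.isfinite(self.fa)]
        if fa_ok.size and (fa_ok.min() < -1e-9 or fa_ok.max() > 1 + 1e-9):
            raise ValueError("fa must lie in [0, 1]")
        norms = np.linalg.norm(self.principal_dir[self.valid], axis=-1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("valid principal_dir vectors must be unit norm")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize(spec: PhantomSpec) -> GroundTruth:
    """Paint regions onto the voxel grid; later regions win where they overlap."""
    shape = spec.shape_yxz
    mu_s = np.full(shape, float(spec.background_mu_s))
    dn = np.zeros(shape)
    axis = np.zeros(shape)
    inc = np.zeros(shape)
    for region in spec.regions:
        if isinstance(region.geometry, Box):  # fast path: direct slicing
            m = region.geometry.slices(shape)
        else:
            m = region.geometry.mask(shape)
        mu_s[m] = region.mu_s
        dn[m] = region.birefringence
        axis[m] = region.axis_deg
        inc[m] = region.through_plane_deg
    dn_app = dn * np.cos(np.deg2rad(inc)) ** 2
    return GroundTruth(
        mu_s=mu_s,
        birefringence=dn,
        birefringence_apparent=dn_app,
        axis_deg=axis,
        through_plane_deg=inc,
        lateral_pixel_um=spec.lateral_pixel_um,
        axial_pixel_um=spec.axial_pixel_um,
        wavelength_um=spec.wavelength_um,
    )


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _apparent_retarder(mu_s, dn, axis_deg, axial_pixel_um, wavelength_um):
    """Cumulative round-trip retarder parameters along depth (last axis).

    Returns (gamma, theta_a): round-trip retardance in radians, wrapped to
    [0, 2*pi], and apparent axis in radians in [0, pi), both per depth pixel.
    """
    half_delta = (np.pi / wavelength_um) * dn * axial_pixel_um  # delta_k / 2, rad
    two_ax = 2.0 * np.deg2rad(axis_deg)
    nz = mu_s.shape[-1]
    lat_shape = mu_s.shape[:-1]
    # cumulative product J(z) = J_z ... J_1
    a00 = np.ones(lat_shape, dtype=complex)
    a01 = np.zeros(lat_shape, dtype=complex)
    a10 = np.zeros(lat_shape, dtype=complex)
    a11 = np.ones(lat_shape, dtype=complex)
    gamma = np.empty(mu_s.shape)
    theta_a = np.empty(mu_s.shape)
    for z in range(nz):
        # per-pixel Jones J_k = R(ax) diag(e^{i d/2}, e^{-i d/2}) R(-ax),
        # built per depth slice to keep the working set small
        c = np.cos(half_delta[..., z])
        s = np.sin(half_delta[..., z])
        sca = s * np.cos(two_ax[..., z])
        b00 = c + 1j * sca
        b01 = 1j * (s * np.sin(two_ax[..., z]))
        b11 = c - 1j * sca
        n00 = b00 * a00 + b01 * a10
        n01 = b00 * a01 + b01 * a11
        n10 = b01 * a00 + b11 * a10
        n11 = b01 * a01 + b11 * a11
        a00, a01, a10, a11 = n00, n01, n10, n11
        # M = J^T J is a linear retarder: M = cos(G/2) I + i sin(G/2) N(2 theta)
        m00 = a00 * a00 + a10 * a10
        m01 = a00 * a01 + a10 * a11
        m11 = a01 * a01 + a11 * a11
        cg = 0.5 * np.real(m00 + m11)
        sc = np.imag(m00 - m11) * 0.5
        ss = np.imag(m01)
        sg = np.hypot(sc, ss)
        gamma[..., z] = 2.0 * np.arctan2(sg, cg)
        theta_a[..., z] = np.mod(np.arctan2(ss, sc), 2.0 * np.pi) / 2.0
    return gamma, theta_a


def _forward_channels(mu_s, dn, axis_deg, spec: PhantomSpec):
    """Noiseless detector channels for per-pixel property arrays (..., nz)."""
    dz_mm = spec.axial_pixel_um / 1000.0
    attenuation = np.exp(-np.cumsum(mu_s, axis=-1) * dz_mm)
    amp = np.sqrt(spec.backscatter_fraction * mu_s) * attenuation
    gamma, theta_a = _apparent_retarder(
        mu_s, dn, axis_deg, spec.axial_pixel_um, spec.wavelength_um
    )
    ch1 = amp * np.abs(np.sin(gamma)) * np.exp(2j * theta_a)
    ch2 = (amp * np.abs(np.cos(gamma))).astype(complex)
    return ch1, ch2


def _add_channel_noise(ch1, ch2, noise_sd, rng):
    """Additive circular complex Gaussian noise, channel 1 first, depth-major."""
    if noise_sd > 0:
        n1 = rng.standard_normal(ch1.shape + (2,))
        ch1 = ch1 + noise_sd * (n1[..., 0] + 1j * n1[..., 1])
        n2 = rng.standard_normal(ch2.shape + (2,))
        ch2 = ch2 + noise_sd * (n2[..., 0] + 1j * n2[..., 1])
    return ch1, ch2


def simulate_ascan(
    mu_s: np.ndarray,
    birefringence: np.ndarray,
    axis_deg: np.ndarray,
    spec: PhantomSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ComplexAScanVolume:
    """Simulate a single A-line from per-depth-pixel optical properties.

    Parameters are 1-D arrays of common length nz: scattering coefficient
    (mm^-1), apparent birefringence dn, and in-plane axis (degrees).
    """
    mu_s = np.asarray(mu_s, dtype=float)
    dn = np.asarray(birefringence, dtype=float)
    ax = np.asarray(axis_deg, dtype=float)
    if not (mu_s.shape == dn.shape == ax.shape) or mu_s.ndim != 1:
        raise ValueError("mu_s, birefringence and axis_deg must be 1-D, same length")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if (mu_s < 0).any() or (dn < 0).any():
        raise ValueError("mu_s and birefringence must be non-negative")
    ch1, ch2 = _forward_channels(mu_s, dn, ax, spec)
    rng = np.random.default_rng(seed)
    ch1, ch2 = _add_channel_noise(ch1, ch2, noise_sd, rng)
    return ComplexAScanVolume(
        ch1=ch1,
        ch2=ch2,
        axial_pixel_um=spec.axial_pixel_um,
        metadata={"noise_sd": noise_sd, "seed": seed},
    )


def simulate_volume(
    spec: PhantomSpec, noise_sd: float = 0.0, seed: int = 0
) -> tuple[ComplexAScanVolume, GroundTruth]:
    """Simulate raw dual-channel data for a whole block, plus ground truth."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    gt = rasterize(spec)
    ch1, ch2 = _forward_channels(gt.mu_s, gt.birefringence_apparent, gt.axis_deg, spec)
    rng = np.random.default_rng(seed)
    ch1, ch2 = _add_channel_noise(ch1, ch2, noise_sd, rng)
    vol = ComplexAScanVolume(
        ch1=ch1,
        ch2=ch2,
        axial_pixel_um=spec.axial_pixel_um,
        metadata={
            "noise_sd": noise_sd,
            "seed": seed,
            "lateral_pixel_um": spec.lateral_pixel_um,
            "wavelength_um": spec.wavelength_um,
        },
    )
    return vol, gt


def tile_offsets(extent: int, tile_px: int, overlap_frac: float) -> list[int]:
    """Nominal tile start positions covering [0, extent) along one axis.

    Step = round(tile * (1 - overlap)); the last tile is clamped to the edge
    (it may overlap its neighbour by more than the nominal fraction).
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    if tile_px > extent:
        raise ValueError(f"tile_px={tile_px} exceeds grid extent {extent}")
    step = max(1, int(round(tile_px * (1.0 - overlap_frac))))
    offsets = list(range(0, max(extent - tile_px, 0) + 1, step))
    if offsets[-1] + tile_px < extent:
        offsets.append(extent - tile_px)
    return offsets


def simulate_tiled_acquisition(
    spec: PhantomSpec,
    tile_px: int,
    overlap_frac: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[ComplexAScanVolume, tuple[int, int]]], GroundTruth]:
    """Simulate a tiled lateral acquisition with the given overlap.

    The block is simulated once and tiles are cut from it, so overlapping
    tile regions contain identical signal and noise; offsets are (y, x)
    nominal positions.  Returns the tile list and the full-grid ground truth.
    """
    vol, gt = simulate_volume(spec, noise_sd=noise_sd, seed=seed)
    ny, nx, _ = spec.shape_yxz
    tiles: list[tuple[ComplexAScanVolume, tuple[int, int]]] = []
    for oy in tile_offsets(ny, tile_px, overlap_frac):
        for ox in tile_offsets(nx, tile_px, overlap_frac):
            sub = ComplexAScanVolume(
                ch1=vol.ch1[oy : oy + tile_px, ox : ox + tile_px],
                ch2=vol.ch2[oy : oy + tile_px, ox : ox + tile_px],
                axial_pixel_um=spec.axial_pixel_um,
                metadata=dict(vol.metadata, offset=(oy, ox)),
            )
            tiles.append((sub, (oy, ox)))
    return tiles, gt


# ---------------------------------------------------------------------------
# diffusion stand-in
# ---------------------------------------------------------------------------


def _fa_from_eigvals(ev: np.ndarray) -> np.ndarray:
    md = ev.mean(axis=-1, keepdims=True)
    num = ((ev - md) ** 2).sum(axis=-1)
    den = (ev**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def simulate_dmri_maps(
    gt: GroundTruth,
    grid_spacing_mm: float = 0.8,
    lambda_parallel: float = 1.2e-3,
    lambda_perp: float = 0.3e-3,
    lambda_background: float = 0.8e-3,
    lambda_free: float = 2.0e-3,
    free_mu_s_max: float = 0.5,
    fa_valid_min: float = 0.05,
) -> DmriMaps:
    """Coarse diffusion parameter maps from the phantom fiber field.

    Each coarse voxel's tensor is the average of per-fine-voxel tensors over
    its lateral footprint and the full slab depth: a prolate tensor aligned
    with the 3-D fiber axis for birefringent voxels, an isotropic tensor for
    background.  Nearly non-scattering voxels (mu_s <= ``free_mu_s_max``,
    the embedding medium) get free-water-like isotropic diffusivity
    ``lambda_free``.  ADC is the mean diffusivity, FA the standard tensor
    anisotropy, principal_dir the leading eigenvector.  Diffusivities are in
    mm^2/s.
    """
    fine_mm = gt.lateral_pixel_um / 1000.0
    if grid_spacing_mm < fine_mm:
        raise ValueError("coarse grid spacing must not be finer than the phantom grid")
    block = max(1, int(round(grid_spacing_mm / fine_mm)))
    ny, nx, _ = gt.mu_s.shape

    theta = np.deg2rad(gt.axis_deg)
    inc = np.deg2rad(gt.through_plane_deg)
    ux = np.cos(inc) * np.cos(theta)
    uy = np.cos(inc) * np.sin(theta)
    uz = np.sin(inc)
    fiber = gt.fiber_mask()

    # voxel-wise tensors (upper triangle), then box-average laterally + in depth
    diff = np.where(fiber, lambda_parallel - lambda_perp, 0.0)
    iso = np.where(fiber, lambda_perp, lambda_background)
    iso = np.where(~fiber & (gt.mu_s <= free_mu_s_max), lambda_free, iso)
    comps = {
        "xx": iso + diff * ux * ux,
        "yy": iso + diff * uy * uy,
        "zz": iso + diff * uz * uz,
        "xy": diff * ux * uy,
        "xz": diff * ux * uz,
        "yz": diff * uy * uz,
    }
    nyc = int(np.ceil(ny / block))
    nxc = int(np.ceil(nx / block))
    coarse = {}
    for k, v in comps.items():
        vd = v.mean(axis=2)  # average over slab depth
        acc = np.zeros((nyc, nxc))
        for iy in range(nyc):
            for ix in range(nxc):
                acc[iy, ix] = vd[
                    iy * block : (iy + 1) * block, ix * block : (ix + 1) * block
                ].mean()
        coarse[k] = acc

    tensors = np.empty((nyc, nxc, 3, 3))
    tensors[..., 0, 0] = coarse["xx"]
    tensors[..., 1, 1] = coarse["yy"]
    tensors[..., 2, 2] = coarse["zz"]
    tensors[..., 0, 1] = tensors[..., 1, 0] = coarse["xy"]
    tensors[..., 0, 2] = tensors[..., 2, 0] = coarse["xz"]
    tensors[..., 1, 2] = tensors[..., 2, 1] = coarse["yz"]

    evals, evecs = np.linalg.eigh(tensors)  # ascending
    adc = evals.mean(axis=-1)
    fa = np.clip(_fa_from_eigvals(evals), 0.0, 1.0)
    principal = evecs[..., :, 2]  # leading eigenvector, (x, y, z) components
    norms = np.linalg.norm(principal, axis=-1, keepdims=True)
    principal = principal / np.where(norms > 0, norms, 1.0)
    valid = fa > fa_valid_min
    return DmriMaps(
        adc=adc,
        fa=fa,
        principal_dir=principal,
        valid=valid,
        grid_spacing_mm=grid_spacing_mm,
    )


# ---------------------------------------------------------------------------
# stock phantoms
# ---------------------------------------------------------------------------


def demo_phantom_spec(
    nx: int = 260,
    ny: int = 260,
    nz: int = 160,
    lateral_pixel_um: float = 30.0,
    wm_mu_s: float = 4.0,
    wm_birefringence: float = 2e-4,
    gm_mu_s: float = 1.0,
    agarose_mu_s: float = 0.2,
    tissue_margin_px: int = 10,
    band_frac: float = 0.385,
) -> PhantomSpec:
    """Two crossing white-matter bundles in a tissue block in agarose.

    A weakly scattering embedding medium surrounds a gray-matter-like block
    holding a horizontal bundle (axis 0 deg) and a vertical bundle (axis
    90 deg) that cross near the centre — enough structure for mosaicking,
    tractography, registration, mask Dice and ROI statistics at desk scale.
    """
    m = tissue_margin_px
    band = int(round(band_frac * ny))
    y0 = (ny - band) // 2
    x0 = (nx - band) // 2
    tissue = Region(
        geometry=Box(x=(m, nx - m), y=(m, ny - m), z=(0, nz)), mu_s=gm_mu_s
    )
    horizontal = Region(
        geometry=Box(x=(m, nx - m), y=(y0, y0 + band), z=(0, nz)),
        mu_s=wm_mu_s,
        birefringence=wm_birefringence,
        axis_deg=0.0,
    )
    vertical = Region(
        geometry=Box(x=(x0, x0 + band), y=(m, ny - m), z=(0, nz)),
        mu_s=wm_mu_s,
        birefringence=wm_birefringence,
        axis_deg=90.0,
    )
    return PhantomSpec(
        grid_shape=(nx, ny, nz),
        lateral_pixel_um=lateral_pixel_um,
        regions=(tissue, horizontal, vertical),
        background_mu_s=agarose_mu_s,
    )


def developmental_series(
    n_ages: int = 5,
    nx: int = 260,
    ny: int = 260,
    nz: int = 160,
    lateral_pixel_um: float = 30.0,
) -> list[dict]:
    """Phantom series emulating progressive myelination across ages.

    With increasing "age": scattering coefficient and birefringence rise
    (denser myelin scatters and retards more), radial diffusivity falls so
    ADC decreases and FA increases.  Returns one dict per age with the
    phantom spec and the diffusion parameters to pass to simulate_dmri_maps.
    """
    mu_s_values = np.linspace(2.0, 6.0, n_ages)
    dn_values = np.linspace(1e-4, 3e-4, n_ages)
    lperp_values = np.linspace(6e-4, 2.5e-4, n_ages)
    series = []
    for i in range(n_ages):
        spec = demo_phantom_spec(
            nx=nx,
            ny=ny,
            nz=nz,
            lateral_pixel_um=lateral_pixel_um,
            wm_mu_s=float(mu_s_values[i]),
            wm_birefringence=float(dn_values[i]),
        )
        series.append(
            {
                "age_index": i,
                "spec": spec,
                "dmri_kwargs": {
                    "lambda_parallel": 1.3e-3,
                    "lambda_perp": float(lperp_values[i]),
                    "lambda_background": 0.9e-3,
                },
            }
        )
    return series
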
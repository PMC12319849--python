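# Methods

`psoctpipe` implements a complete desk-scale analogue of a serial-sectioning
polarization-sensitive OCT (PSOCT) study of white-matter myelination and its
comparison against diffusion MRI parameter maps.  Physical specimens are
replaced by a synthetic birefringent phantom with known ground truth, so
every stage — reconstruction, en-face mosaicking, tractography,
co-registration, ROI statistics — is testable end to end.

## Forward model (phantom)

Each specimen is a voxel grid (default 260 x 260 lateral x 160 depth pixels)
of scattering coefficient µs (mm⁻¹), birefringence Δn, in-plane fiber axis
θ ∈ [0°, 180°) and through-plane inclination.  The stock phantom is a
gray-matter-like block (µs = 1 mm⁻¹) embedded in weakly scattering agarose
(µs = 0.2 mm⁻¹) containing two orthogonal crossing bundles (axes 0° and
90°).

Light propagation is single-backscatter with no multiple scattering or
diattenuation.  The backscattered amplitude at depth pixel z is

    A(z) = sqrt(β µs(z)) · exp(−Σ_{j≤z} µs(j) Δ),

with backscatter fraction β = 0.01 (configurable; the value only scales
signal against noise) and Δ the axial pixel size (4.2 µm in tissue,
converted to mm at the single point of use).  Squaring A gives the correct
double-pass intensity attenuation exp(−2 Σ µs Δ).

Polarization is propagated through per-pixel linear-retarder Jones matrices
J_k = R(θ_k) D(δ_k) R(−θ_k), δ_k = (2π/λ) Δn_k Δ, λ = 1.3 µm.  The round
trip uses the transpose product M(z) = J(z)ᵀ J(z), standard for
reflection-mode PSOCT; M is itself a linear retarder whose retardance Γ(z)
is the cumulative *double-pass* retardation and whose axis is the apparent
optic axis.  The detector model is idealized: channel amplitudes
A·|sin Γ| and A·|cos Γ| with phase difference 2θ_a, defined directly on the
retarder decomposition of M so that the reconstruction identities below
hold exactly for a uniform-axis medium.  A physical dual-channel
interferometer adds instrument phase factors that cancel in the same
ratios; we do not model them.  For layered (non-uniform-axis) media the
reconstructed retardance/axis are the *apparent* values of M — exact
recovery tests therefore use uniform-axis phantoms only.  Through-plane
fibers scale apparent birefringence by cos²(inclination), the standard
projection effect, reproducing the low-retardance appearance of
through-plane tracts.  One more real wrapping effect is reproduced: once
the cumulative round-trip retardance passes 2π, the apparent axis of M
flips by 90°, so axis-recovery checks keep the cumulative retardance below
one wrap.

Noise is additive circular complex Gaussian per channel (per-quadrature
standard deviation `noise_sd`, default 1e-3 against a surface signal
amplitude of ~0.1–0.25), drawn from one seeded stream, channel 1 first.
Speckle, spectral roll-off, dispersion and depolarization are not modeled:
passing tests demonstrate correctness of the estimators and pipeline
plumbing, not robustness to those real-data effects.

Tiled acquisition cuts tiles from one simulated block with 20% overlap;
nominal offsets step by round(tile·(1−overlap)) with the last tile clamped
to the grid edge, so coverage is guaranteed.  Because tiles are cut from
one realization, overlap regions agree exactly — the stitching round trip
is an identity check, not a noise-averaging one.

## Diffusion stand-in

Coarse maps (0.8 mm grid) are produced from the same fiber field: each
coarse voxel averages per-fine-voxel tensors over its lateral footprint and
the slab depth — a prolate tensor (λ∥ = 1.2–1.3e-3, λ⊥ = 0.25–0.6e-3 mm²/s,
in-vivo-like magnitudes) aligned with the 3-D fiber axis in bundles, an
isotropic tensor in gray matter (0.8–0.9e-3) and free-water-like agarose
(2.0e-3).  ADC is the mean diffusivity, FA the standard tensor anisotropy,
and the principal direction the leading eigenvector (flagged invalid below
FA 0.05).  Mixed-orientation voxels necessarily show reduced FA, which is
what makes the retardance–FA comparison scientifically interesting.

## Reconstruction

From dual-channel complex profiles A1 e^{iφ1}, A2 e^{iφ2}:

* reflectivity R = A1² + A2² (proportionality constant fixed at 1 — all
  downstream use is ratio- or correlation-based);
* retardance δ = arctan(A1/A2) ∈ [0°, 90°], NaN when both channels vanish;
* axis θ = wrap(φ1−φ2 into [0°, 360°))/2 ∈ [0°, 180°), NaN where the
  cross-polarized amplitude is at or below the SNR floor (default
  3·noise_sd when the noise level is known, else 0 — the axis is pure noise
  without cross-polarized signal);
* scattering coefficient µs(z) = I(z) / (2 Δ Σ_{j=z+1..d} I(j)) with I the
  linear reflectivity (the estimator's derivation requires linear
  intensities, not dB).

The finite tail sum is implemented exactly as written.  Its known artifact:
when µs·Δ·d is small the truncated tail under-counts the remaining signal
and µs is overestimated, increasingly toward the bottom of the imaging
range and severely for weakly scattering media (agarose reconstructs near
1 mm⁻¹ rather than 0.2 at this depth budget).  An optional tail-truncation
parameter trims trailing pixels; the last pixel and zero-tail pixels are
NaN.  Consequence for masking: tissue-vs-agarose contrast is taken from the
en-face *reflectivity* (log scale), which preserves the backscatter
contrast; µs is used for the white-vs-gray split, where its contrast is
strong.

When starting from spectral fringes, the spectral-to-depth transform is a
mean-subtracted (DC-removed) inverse DFT keeping the positive-frequency
half.

## En-face maps, stitching, stacking

Scalar volumes collapse by NaN-ignoring means over a configurable depth
range (default the first 80 pixels ≈ 336 µm, chosen so the deepest white
matter still sits well above the noise floor at the largest µs in the
series; µs is computed per voxel and then averaged).  Orientation collapses
to the center of the peak 5° histogram bin (ties to the lowest bin, for
determinism; the center is the unbiased within-bin choice), making the
estimator bin-quantized by construction — orientation comparisons carry a
±2.5° quantization floor.

Tiles fuse by linear blending: per-tile weights ramp linearly from
(d+1)/(O+1) at the tile edge to 1 at distance ≥ overlap width O, normalized
to sum to one over contributing tiles (the +1 keeps edge pixels defined).
Orientation maps blend as doubled-angle unit vectors and are halved back —
naive averaging of axial angles fails across the 0°/180° seam.  Nominal
offsets are trusted by default; optional phase-correlation refinement
(±5 px) exists for data with stage error.  Serial sections stack by plain
concatenation with the slice thickness (100–150 µm class) recorded as the
section-axis spacing; blockface geometry needs no inter-slice registration.

## Tractography

A native 2-D FACT-style tracker runs on the en-face axial orientation
field, masked to white matter by a retardance threshold (Otsu by default —
the threshold has no canonical value, and the retardance histogram of a
section is strongly bimodal).  Direction lookup is nearest-neighbor
(optionally doubled-angle bilinear); axial data has no sign, so the step
sign continues the previous step and every seed spawns both directions.
Termination: leaving mask/bounds, axial orientation change above the 45°
threshold, NaN, or the length cap.  Defaults: step 0.5 px, seed grid 5 px,
minimum length 10 px.  Euler integration on a curved field drifts by
O(step) per step — on an analytic circular field of radius 60 px at step
0.25 px the radius drifts ~1.3% per revolution, the measured figure frozen
in the tests.

## Co-registration

ADC is registered to the µs mosaic (the pair with the strongest
gray/white contrast) by maximizing normalized cross-correlation over a
6-parameter affine (rotation, log-scales, shear, translation), Powell
search coarse-to-fine over a 3-level pyramid, initialized by the pixel-size
ratio and center-of-mass alignment.  The moving image is negated first:
ADC and µs contrast are anti-correlated, and fixing the polarity keeps the
optimum deterministic.  The rotational component is extracted by polar
decomposition (unique, with a symmetric positive-definite remainder, unlike
QR) and applied to the diffusion principal directions before in-plane
projection; projected magnitude below 0.1 flags a through-plane fiber with
no meaningful in-plane angle.  Dice = 2|A∩B|/(|A|+|B|) scores mask overlap
(two empty masks define Dice 1, avoiding NaN on degenerate fixtures).
Registration accuracy is validated by recovering a known applied affine on
a synthetic µs/ADC pair at comparable resolution; at 0.8 mm a white-matter
mask a few millimetres across is too coarsely quantized for a sub-pixel
Dice criterion to be meaningful, so the coarse-grid registration is
exercised but scored only descriptively.

## ROI statistics

ROIs are 0.9 x 0.9 mm boxes on a regular lattice (stride = ROI side) kept
when their white-matter fraction reaches 0.8 — a reproducible replacement
for manual placement; when more than the requested count survive they are
subsampled with a deterministic even stride.  Per ROI: NaN-ignoring means
of µs, retardance, ADC, FA and axial circular means of both orientation
sources (double the angles, average unit vectors, halve the argument;
resultant length < 1e-9 is degenerate → NaN).  Angular disagreement uses
the half-circle metric min(|a−b| mod 180, 180 − |a−b| mod 180), so 178°
vs 1° is 3°.  Diffusion values are sampled after resampling/reorientation
onto the PSOCT grid.  Correlations are Pearson on pairwise-complete ROIs
(pooled across ages by default); map summaries use population (n) standard
deviation.  No significance testing — the analysis reports r values and
distributions only.

## Desk-scale study conditions

The developmental series has five "ages": bundle µs 2 → 6 mm⁻¹ and Δn
1e-4 → 3e-4 (monotone, spanning a tissue-plausible range), radial
diffusivity 6e-4 → 2.5e-4 mm²/s at fixed axial diffusivity, so ADC falls
and FA rises with age.  The pipeline default grid uses 30 µm lateral pixels
(so 0.9 mm ROIs and 0.8 mm diffusion voxels fit a 7.8 mm section at
manageable cost) with 4.2 µm axial pixels, 150 px tiles at 20% overlap,
noise_sd 1e-3.  With these conditions each age yields 33 white-matter ROIs
and the pooled correlations recover the expected signs strongly
(r(µs, ADC) < 0, r(retardance, FA) > 0); the magnitudes are properties of
the synthetic design, not estimates of tissue values.

## Numerical conventions

Angles: degrees, [0, 180), CCW from +x, NaN invalid — everywhere.
Coordinates: 0-based pixel centers, x = column, y = row; transforms map
moving to fixed pixel coordinates.  Maps: float32 TIFF with JSON sidecar
(pixel sizes µm) or NIfTI (pixdim in mm).  Streamlines: NDJSON always,
TrackVis .trk additionally.  Config: strict YAML schema — unknown keys are
errors, because silently ignored options are the dominant pipeline failure
mode.  All randomness flows from one integer seed; per-age seeds are
derived deterministically below 2³¹.

## Known limitations

No speckle or confocal/roll-off modeling; no depth-resolved (local)
birefringence unmixing — retardance is cumulative; no 3-D tractography and
no through-plane angle (not measurable with this contrast); registration is
affine only (blockface geometry is distortion-free by construction); the
µs estimator's tail bias is reproduced, not corrected.
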
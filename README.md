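# psoctpipe

Quantitative white-matter imaging couples two very different modalities:
serial-sectioning **polarization-sensitive OCT (PSOCT)**, which measures
tissue reflectivity, cumulative retardance δ, in-plane optic-axis
orientation θ and the depth-resolved scattering coefficient µs at
micrometre scale, and **diffusion MRI**, which measures ADC, FA and fiber
direction at millimetre scale.  Myelin is both birefringent and strongly
scattering, so µs and δ rise as white matter myelinates, while ADC falls
and FA rises — making the cross-modal comparison a sensitive consistency
check for developmental myelination mapping.

`psoctpipe` is an analysis pipeline for exactly this comparison, built to
run entirely on synthetic specimens with known ground truth:

* **phantom** — birefringent fiber phantoms (Jones-matrix forward model,
  exponential single-scatter decay, tiled acquisition with 20% overlap)
  plus matched 0.8 mm diffusion-tensor parameter maps;
* **recon** — the PSOCT estimators: R(z) = A1² + A2²,
  δ(z) = arctan(A1/A2), θ(z) = (φ1−φ2)/2, and the depth-resolved
  attenuation estimator µs(z) = I(z) / (2Δ Σ_{j=z+1..d} I(j));
* **enface** — depth collapse (mean for scalars, peak of a 5° histogram
  for orientation), linear-blend tile stitching (axial-safe for angles),
  serial-section stacking;
* **tract2d** — FACT-style streamline tractography on the 2-D axial
  orientation field, retardance-masked, 45° angular termination;
* **coreg** — multiresolution NCC affine registration of ADC to µs, Dice
  mask overlap, and reorientation of diffusion vectors by the rotational
  (polar-decomposition) component of the affine;
* **roistats** — 0.9 × 0.9 mm white-matter ROIs, axial circular means
  (angle doubling), polar-space angular differences
  (178° − 1° = 3°, not 177°), Pearson correlations.

## Worked example

The numbered scripts under `analysis/` walk through the study; the whole
pipeline is one command:

```bash
python analysis/05_roi_correlations.py --seed 0
```

which simulates five specimens of increasing "age" (µs 2→6 mm⁻¹,
Δn 1e-4→3e-4, radial diffusivity falling), reconstructs and stitches each
tiled acquisition, tracks fibers, registers the diffusion maps, pools the
white-matter ROIs and prints:

```
165 pooled white-matter ROIs across 5 ages
r(mu_s, ADC)        = -0.974  (expected negative: denser myelin scatters more and restricts diffusion)
r(retardance, FA)   = +0.912  (expected positive: both track fiber anisotropy)
r(retardance, ADC)  = -0.975
r(mu_s, FA)         = +0.912
median PSOCT-dMRI angular difference: 0.2 deg
```

The signs are the scientific content: scattering anti-correlates with
diffusivity and retardance correlates with anisotropy as myelination
proceeds, and the two modalities' fiber orientations agree to well within
the 5° histogram quantization of the PSOCT orientation estimator.  Per-age
artifacts (parameter-map TIFFs, streamlines in NDJSON/.trk, transforms,
ROI tables, the polar angular-difference plot) land under
`results/developmental/`.  The same pipeline is exposed as a CLI
(`psoctpipe run-all`, plus per-stage subcommands `simulate`, `reconstruct`,
`enface`, `stitch`, `track`, `register`, `correlate`, `report`).

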
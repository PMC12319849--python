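#!/usr/bin/env python
"""Reconstruct one specimen's tiled acquisition and stitch the mosaic.

Simulates the middle-age specimen, reconstructs reflectivity, retardance,
optic-axis orientation and the depth-resolved scattering coefficient per
tile, collapses them to en-face maps (5-degree histogram peak for the
orientation) and fuses the tiles by linear blending.  Writes the stitched
parameter maps and prints how well they recover the known optical
properties.
"""

import argparse
from pathlib import Path

import numpy as np

from psoctpipe import pipeline
from psoctpipe.config import load_config
from psoctpipe.io import write_map
from psoctpipe.roistats import angular_difference


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--age", type=int, default=2)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out / "enface"
    out.mkdir(parents=True, exist_ok=True)

    cfg = load_config(**{"seed": args.seed})
    sample = pipeline.simulate_age(cfg, args.age)
    sample = pipeline.reconstruct_and_stitch(cfg, sample)
    st = sample.stack
    for name, arr in (("mu_s", st.mu_s_map), ("retardance", st.retardance_map),
                      ("orientation", st.orientation_map)):
        write_map(out / f"age{args.age}_{name}.tif", arr, st.pixel_um)

    gt = sample.gt
    wm = gt.fiber_mask()[..., 0]
    true_mu = gt.mu_s[..., 0][wm].mean()
    est_mu = np.nanmean(st.mu_s_map[wm])
    d = angular_difference(st.orientation_map[wm], gt.axis_deg[..., 0][wm])
    print(f"stitched mosaic {st.shape}, {len(sample.tiles)} tiles, 20% overlap")
    print(f"white-matter mu_s: truth {true_mu:.2f} mm^-1, en-face estimate "
          f"{est_mu:.2f} mm^-1 ({100 * (est_mu / true_mu - 1):+.1f}% — the "
          "finite-depth tail bias of the attenuation estimator)")
    print(f"orientation: median axial error {np.nanmedian(d):.2f} deg "
          "(bin-quantized at 5 deg)")


if __name__ == "__main__":
    main()
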
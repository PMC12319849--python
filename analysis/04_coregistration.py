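#!/usr/bin/env python
"""Register the diffusion ADC map to the PSOCT scattering map.

The 0.8 mm ADC map (contrast-inverted, since ADC is low where mu_s is
high) is aligned to the 30 um scattering-coefficient mosaic by
multiresolution NCC-affine registration.  Registration quality is scored
by Dice overlap of tissue and white-matter masks; the rotational component
of the affine then carries the diffusion principal directions into the
PSOCT plane.
"""

import argparse
from pathlib import Path

from psoctpipe import pipeline
from psoctpipe.config import load_config
from psoctpipe.io import write_json


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--age", type=int, default=2)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out / "coregistration"
    out.mkdir(parents=True, exist_ok=True)

    cfg = load_config(**{"seed": args.seed})
    sample = pipeline.simulate_age(cfg, args.age)
    sample = pipeline.reconstruct_and_stitch(cfg, sample)
    sample = pipeline.run_tractography(cfg, sample)
    sample = pipeline.register_and_map(cfg, sample)
    write_json(out / "transform.json", sample.transform.to_dict())
    write_json(out / "dice.json", sample.dice_scores)
    print(f"recovered in-plane rotation {sample.transform.rotation_deg:+.2f} deg "
          "(the modalities are simulated aligned, so near zero is correct)")
    print(f"Dice overlap: tissue {sample.dice_scores['tissue']:.3f}, "
          f"white matter {sample.dice_scores['wm']:.3f}")
    print("residual disagreement is 0.8 mm voxel quantization at mask edges.")


if __name__ == "__main__":
    main()
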
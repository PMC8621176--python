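#!/usr/bin/env python
"""Optional reproduction on the DRIVE retinal-vessel dataset.

NOT part of the test or acceptance surface: it requires a manual download
(registration at https://drive.grand-challenge.org/) and the original
experiments' parameter values were never published, so the numbers here
depend on the parameters you pass.

Protocol: each manual segmentation mask is used as the clean image, additive
Gaussian noise with standard deviation 100 is applied, the two-player model
is run on the noisy image, the result is thresholded, and DICE/Jaccard are
computed against the mask itself.  Mean and standard deviation over all
images are printed.

Usage:
    python scripts/reproduce_drive.py /path/to/DRIVE/training/1st_manual \
        --sigma 100 --lambda1 0.01 --tau 128
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

from nashseg.admm_solver import run_game
from nashseg.cli_io import load_image
from nashseg.metrics import dice, jaccard
from nashseg.model_core import SolverParams
from nashseg.phantoms import add_noise
from nashseg.segmenter import threshold_binary


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("mask_dir", type=Path,
                    help="directory with the manual segmentation masks (gif/png/tif)")
    ap.add_argument("--sigma", type=float, default=100.0)
    ap.add_argument("--tau", type=float, default=128.0)
    ap.add_argument("--lambda1", type=float, default=0.01)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args(argv)

    paths = sorted(
        p for p in args.mask_dir.iterdir()
        if p.suffix.lower() in (".gif", ".png", ".tif", ".tiff")
    )
    if not paths:
        print(f"no mask images found in {args.mask_dir}", file=sys.stderr)
        return 1

    params = SolverParams(
        lambda1=args.lambda1, mu1=0.01, xi1=0.1, rho1=0.1,
        lambda2=0.1, mu2=0.1, xi2=0.5, rho2=1.0, max_outer=500, tol=1e-5,
    )
    dices, jaccards = [], []
    for i, path in enumerate(paths):
        mask = (load_image(path) > 0).astype(float)
        noisy = add_noise(mask * 255.0, args.sigma, seed=args.seed + i)
        state, _ = run_game(noisy, params)
        seg = threshold_binary(state.g, args.tau)
        d = dice(seg, mask.astype(int))
        j = jaccard(seg, mask.astype(int))
        dices.append(d)
        jaccards.append(j)
        print(f"{path.name}: DICE {d:.4f}  JACCARD {j:.4f}")

    print(f"\nDICE    {np.mean(dices):.3f} +/- {np.std(dices):.3f}")
    print(f"JACCARD {np.mean(jaccards):.3f} +/- {np.std(jaccards):.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
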
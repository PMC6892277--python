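#!/usr/bin/env python
"""Generate the synthetic cohort: three whole-placenta phantom stacks and a
set of micrograph scenes, with their ground truth.

Image data (TIFF stacks, micrographs) goes under scratch/phantoms/; the
small ground-truth summaries go to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from placvasc.experiments import recovery_spec
from placvasc.phantom import (
    generate_micrograph_phantom,
    generate_volume_phantom,
    random_micrograph_spec,
)
from placvasc.stackio import write_stack

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-placentas", type=int, default=3)
    args = ap.parse_args()

    scratch = ROOT / "scratch" / "phantoms"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    for i in range(args.n_placentas):
        spec = recovery_spec(0.05, seed=args.seed + i)
        volume, truth = generate_volume_phantom(spec)
        stack_dir = scratch / f"placenta_{i}" / "stack"
        write_stack(volume, stack_dir)
        pd.DataFrame(
            {
                "z": truth.centreline_voxels[:, 0],
                "y": truth.centreline_voxels[:, 1],
                "x": truth.centreline_voxels[:, 2],
                "radius_vox": truth.radius_vox,
                "radius_um": truth.radius_um,
            }
        ).to_csv(scratch / f"placenta_{i}" / "centreline_truth.csv", index=False)
        rows.append(
            {
                "placenta_id": f"P{i}",
                "stack_dir": str(stack_dir),
                "cord_y": truth.cord_point[0],
                "cord_x": truth.cord_point[1],
                "true_density_pct": 100.0 * truth.global_density,
                "n_trees": spec.n_trees,
            }
        )
    cohort = pd.DataFrame(rows)
    cohort.to_csv(results / "phantom_cohort.csv", index=False)

    mani = []
    for i in range(6):
        spec2d = random_micrograph_spec(seed=args.seed + 100 + i,
                                        perfused_probability=0.8)
        img, masks, _ = generate_micrograph_phantom(spec2d)
        p = scratch / "micrographs" / f"mic_{i}.tif"
        p.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(p, img)
        mani.append({"placenta_id": "P0", "block_id": f"b{i // 2}",
                     "image": str(p), "position": "basal", "um_per_px": 1.0})
    pd.DataFrame(mani).to_csv(results / "micrograph_manifest.csv", index=False)

    print(f"wrote {args.n_placentas} phantom stacks and 6 micrographs")
    print(cohort.to_string(index=False,
                           float_format=lambda v: f"{v:.2f}"))
    print(f"mean true vascular density: "
          f"{np.mean(cohort.true_density_pct):.2f}%")


if __name__ == "__main__":
    main()
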
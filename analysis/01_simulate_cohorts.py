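#!/usr/bin/env python
"""Simulate the matched cohorts and their omentum-like CT slices.

Generates the default study conditions — 41 stage-matched occult/control
pairs for the test cohort and 10 for the validation cohort — writes the
cohort tables to results/cohorts/, and saves a handful of example images
with their ROI polygons so the synthetic data can be inspected.
"""

import sys
from pathlib import Path

from omentex import SimConfig, gen_cohort
from omentex.io import write_cohort_csv, write_image_png, write_roi_json

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/cohorts")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    test, validation, images = gen_cohort(cfg, with_images=True)
    write_cohort_csv(test, OUT / "test_cohort.csv")
    write_cohort_csv(validation, OUT / "validation_cohort.csv")

    example_dir = OUT / "example_images"
    example_dir.mkdir(exist_ok=True)
    for pid in list(test["patient_id"][:2]) + list(validation["patient_id"][:2]):
        image, verts = images[pid]
        write_image_png(image, example_dir / f"{pid}.png")
        write_roi_json(verts, example_dir / f"{pid}_roi.json")

    print(f"test cohort: {len(test)} patients ({test['pair_id'].nunique()} pairs)")
    print(f"validation cohort: {len(validation)} patients ({validation['pair_id'].nunique()} pairs)")
    print(f"wrote cohort tables and {4} example image/ROI pairs under {OUT}")


if __name__ == "__main__":
    main()
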
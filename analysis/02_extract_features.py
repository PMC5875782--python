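#!/usr/bin/env python
"""Extract the seven ROI texture features for every simulated patient.

Regenerates the same cohorts and images as 01_simulate_cohorts.py (the
generator is a pure function of the seed), computes average, SD, kurtosis,
skewness, entropy, GLCM correlation (both normalizations) and contrast for
each patient's ROI, and writes feature-augmented cohort tables under
results/features/.
"""

import sys
from pathlib import Path

from omentex import SimConfig, gen_cohort
from omentex.io import write_cohort_csv
from omentex.pipeline import extract_cohort_features

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/features")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    test, validation, images = gen_cohort(cfg, with_images=True)
    test = extract_cohort_features(test, images)
    validation = extract_cohort_features(validation, images)
    write_cohort_csv(test, OUT / "test_features.csv")
    write_cohort_csv(validation, OUT / "validation_features.csv")

    med = test.groupby("group")[["average", "std_dev", "entropy", "correlation_standard"]].median()
    print("test-cohort medians by group:")
    print(med.round(3).to_string())
    print(f"wrote feature tables under {OUT}")


if __name__ == "__main__":
    main()
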
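#!/usr/bin/env python
"""Entropy ROC on the test cohort and frozen-cutoff validation (tables 3-4).

Builds the empirical ROC of entropy over the 82 test-cohort patients,
selects the operating point furthest from the chance diagonal (maximal
Youden J), then applies that cutoff — frozen — to the 20 validation-cohort
patients and reports the confusion table and diagnostic performance.
"""

import json
from pathlib import Path

import pandas as pd

from omentex import apply_cutoff, optimal_cutoff, roc_curve
from omentex.io import read_cohort_csv

IN = Path("results/features")
OUT = Path("results/roc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    test = read_cohort_csv(IN / "test_features.csv")
    validation = read_cohort_csv(IN / "validation_features.csv")

    curve = roc_curve(test["entropy"], test["group"])
    cut = optimal_cutoff(curve)
    pd.DataFrame(
        {"threshold": curve.thresholds, "sensitivity": curve.sensitivity, "specificity": curve.specificity}
    ).to_csv(OUT / "roc_points.csv", index=False)

    conf, metrics = apply_cutoff(validation["entropy"], validation["group"], cut.threshold)
    summary = {
        "auc": round(curve.auc, 3),
        "auc_ci_95": [round(v, 3) for v in curve.auc_ci_95],
        "cutoff": round(cut.threshold, 3),
        "rule": cut.rule,
        "test_sensitivity": round(cut.sensitivity, 3),
        "test_specificity": round(cut.specificity, 3),
        "validation": {
            "tp": conf.tp,
            "fp": conf.fp,
            "fn": conf.fn,
            "tn": conf.tn,
            "sensitivity": round(metrics["sensitivity"], 3),
            "specificity": round(metrics["specificity"], 3),
        },
    }
    (OUT / "roc_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"test AUC {summary['auc']} (95% CI {summary['auc_ci_95'][0]}-{summary['auc_ci_95'][1]})")
    print(f"optimal cutoff: entropy > {summary['cutoff']} "
          f"(test sens {summary['test_sensitivity']}, spec {summary['test_specificity']})")
    v = summary["validation"]
    print(f"validation: sens {v['sensitivity']} ({v['tp']}/{v['tp'] + v['fn']}), "
          f"spec {v['specificity']} ({v['tn']}/{v['tn'] + v['fp']})")
    print(f"wrote {OUT / 'roc_summary.json'}")


if __name__ == "__main__":
    main()
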
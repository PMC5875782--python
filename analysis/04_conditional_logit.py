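#!/usr/bin/env python
"""Conditional logistic regression on the matched test cohort (table 2).

Enters the four heterogeneity features (average, GLCM correlation, entropy,
SD) into a 1:1 conditional logistic model.  With strongly co-determined
covariates the fit can be unstable or even separate — both outcomes are
reported explicitly rather than hidden.
"""

from pathlib import Path

from omentex import clogit_fit
from omentex.io import read_cohort_csv

IN = Path("results/features/test_features.csv")
OUT = Path("results/stats")
COVARIATES = ["average", "correlation_paper_scale", "entropy", "std_dev"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    test = read_cohort_csv(IN)
    fit = clogit_fit(test, COVARIATES)
    if fit.separation_detected:
        print("separation detected: the four features jointly classify every pair;")
        print("no finite coefficient estimates exist (monotone likelihood).")
        (OUT / "table2_note.txt").write_text(
            "conditional logit: separation detected; no estimates reported\n"
        )
        return
    frame = fit.summary_frame().round(4)
    frame.to_csv(OUT / "table2.csv")
    print(f"converged: {fit.converged}, pairs used: {fit.n_pairs_used}")
    print(frame.to_string())
    print(f"wrote {OUT / 'table2.csv'}")


if __name__ == "__main__":
    main()
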
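#!/usr/bin/env python
"""Univariate matched comparison of clinical and texture features (table 1).

Compares the occult and control groups of the test cohort: paired Wilcoxon
signed-rank tests for continuous variables, Fisher's exact test for
categorical ones, against the Bonferroni-adjusted level 0.05/12.  Uses the
feature tables written by 02_extract_features.py.
"""

from pathlib import Path

from omentex import univariate_table
from omentex.io import read_cohort_csv

IN = Path("results/features/test_features.csv")
OUT = Path("results/stats")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    test = read_cohort_csv(IN)
    tbl = univariate_table(test)
    tbl.to_csv(OUT / "table1.csv", index=False)
    sig = tbl[tbl["significant"]]
    print(f"{len(sig)} of {len(tbl)} comparisons significant at alpha = 0.05/12:")
    for row in sig.itertuples():
        print(f"  {row.variable:12s} p = {row.p_value:.2e}")
    print(f"wrote {OUT / 'table1.csv'}")


if __name__ == "__main__":
    main()
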
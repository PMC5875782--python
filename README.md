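# omentex

CT texture analysis of the omentum for predicting **occult peritoneal
carcinomatosis** in advanced gastric cancer — a matched case-control
radiomics pipeline, exercised end-to-end on synthetic CT-like images.

Occult peritoneal carcinomatosis is seeding that preoperative CT misses and
surgery finds; predicting it from the *texture* of the seemingly normal
omental fat could spare patients futile laparotomy. This package implements
the full analysis chain for that question, for researchers who want to run,
stress-test or extend it:

1. **Texture features** — a polygonal ROI over the omentum is rasterized
   (pixel-center rule) and seven features are computed from the enclosed
   gray values: average, standard deviation, skewness, excess kurtosis,
   first-order entropy *H* = −Σ pᵢ log₂ pᵢ (bits), and GLCM contrast
   Σ p(i,j)(Lᵢ−Lⱼ)² and correlation Σ p(i,j)(Lᵢ−μₓ)(Lⱼ−μ_y)/(σₓσ_y)
   (distance 1, four directions pooled, symmetric; a variance-product
   normalization of the correlation is also provided — see
   `docs/methods.md`).
2. **Matched statistics** — paired Wilcoxon signed-rank (exact by
   enumeration for ≤ 15 pairs) and Fisher's exact tests, Bonferroni-adjusted
   (α/12); conditional logistic regression for 1:1 pairs via the
   within-pair-difference likelihood, Newton–Raphson, Wald inference, with
   explicit separation detection.
3. **ROC evaluation** — empirical ROC with strict `score > t` positivity,
   Mann–Whitney AUC with DeLong 95% CI, cutoff at the point furthest from
   the chance diagonal (max Youden J), and frozen-cutoff application to a
   held-out validation cohort (sensitivity, specificity, PPV, NPV).
4. **Synthetic data** — omentum-like Gaussian-field images with
   group-dependent heterogeneity and simulated stage-matched cohorts
   (41 test + 10 validation pairs by default), so every stage is testable
   with no data download.

## Worked example

```bash
python analysis/01_simulate_cohorts.py 1     # 41 + 10 matched pairs, images
python analysis/02_extract_features.py 1     # seven features per patient
python analysis/03_univariate_stats.py       # table 1: matched comparisons
python analysis/04_conditional_logit.py      # table 2: conditional logit
python analysis/05_roc_cutoff_validation.py  # ROC, cutoff, frozen validation
```

With seed 1 the feature extraction prints

```
test-cohort medians by group:
         average  std_dev  entropy  correlation_standard
group
control  920.048   14.681    5.881                 0.908
occult   920.574   23.688    6.576                 0.361
```

— the occult group has higher SD and entropy and lower GLCM correlation, the
direction structure the pipeline is designed to detect. The univariate stage
then finds the heterogeneity features (entropy, SD, contrast, correlation)
significant at the Bonferroni level while all clinical variables stay null,
and the ROC stage prints

```
test AUC 0.986 (95% CI 0.968-1.0)
optimal cutoff: entropy > 6.178 (test sens 1.0, spec 0.902)
validation: sens 1.0 (10/10), spec 1.0 (10/10)
```

meaning: the entropy threshold 6.178 chosen on the test cohort, applied
frozen, classifies the synthetic validation cohort perfectly (the
image-backed generator produces a stronger effect than real cohorts; the
feature-level generator reproduces realistic overlap — `docs/methods.md`
discusses both regimes). The same stages are available as a CLI
(`omentex simulate|extract|stats|roc|validate|run-all`) and as plain library
calls.

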
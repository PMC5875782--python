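# Methods

This note documents the statistical and computational choices in `omentex`:
what each stage computes, which conventions were adopted where several are in
use, and what the synthetic data generator does and does not emulate.

## Study design being modelled

The pipeline reproduces a matched case-control radiomics analysis: patients
with advanced gastric cancer whose peritoneal carcinomatosis was *occult*
(found only at surgery, invisible on preoperative CT) are each paired with a
control patient matched one-to-one on clinical T and N stage. Texture
features of a polygonal ROI over the omental fat on a single axial CT slice
are compared between groups in a test cohort (41 pairs), a multivariable
conditional logistic model identifies independent predictors, an ROC cutoff
for the leading predictor (entropy) is chosen on the test cohort, and that
cutoff is applied frozen to a validation cohort (10 pairs). The package
operates on supplied 2D slices; slice selection from a 3D volume and CT
acquisition are out of scope.

Gray values are *stored values* = Hounsfield units + 1024 throughout, so
omental fat (≈ −104 HU) sits near 920. A `signed_hu` flag accepts signed HU
and applies the offset internally.

## Texture features

A pixel belongs to the ROI iff its center `(x + 0.5, y + 0.5)` lies inside
the polygon; the polygon must be simple (validated via shapely). Features are
computed on the masked gray values only:

* **average, standard deviation** — arithmetic mean and sample SD
  (divisor n − 1).
* **skewness, excess kurtosis** — moment coefficients `m3 / m2^{3/2}` and
  `m4 / m2² − 3` on bias-uncorrected central moments. Kurtosis uses the
  excess convention because values reported for omental ROIs cluster around
  0 with negative quartiles, which is impossible on the Pearson (3-centered)
  scale. Constant ROIs yield NaN markers, never 0.
* **entropy** — first-order Shannon entropy in bits of the histogram with
  one bin per distinct integer gray value. First-order (not co-occurrence)
  entropy is used because reported values of 6.8–7.5 bits against ROIs of
  ~770 pixels (max log₂ 770 ≈ 9.6) are only attainable by a histogram
  entropy.
* **GLCM contrast and correlation** — from a gray-level co-occurrence matrix
  at distance 1 pooled over the four canonical directions (0°, 45°, 90°,
  135°), symmetrized; both pixels of a pair must lie inside the mask. Levels
  are the raw integer gray values present in the ROI; a `levels` option
  rebins for robustness studies. Distance-1/four-direction pooling is the
  canonical Haralick choice; the settings are recorded in every output.
* **correlation normalization** — two variants are always computed. The
  *standard* variant is the Pearson form, covariance over the product of
  marginal SDs, in [−1, 1]. The *paper_scale* variant divides the covariance
  by the product of marginal *variances*; clinical texture packages that
  report omental correlations of order 10⁻³ are consistent with this
  normalization and not with the standard one (a standard correlation of
  0.002 would be indistinguishable from noise, while σ² ≈ 15–25² makes the
  variance-product form land exactly in that range). The paper_scale variant
  is not invariant under intensity scaling; pipeline outputs default to it
  for comparability, with the standard value reported alongside.

Invariants enforced by tests: GLCM probabilities sum to 1 and the
symmetrized matrix equals its transpose; contrast and entropy are invariant
under adding a constant to all gray values; standard correlation is
affine-invariant; entropy is bounded by log₂(pixel count) and log₂(distinct
levels); all GLCM functionals equal a brute-force pair-enumeration oracle to
1e-10 on small images.

## Univariate statistics

Continuous variables use the paired Wilcoxon signed-rank test on
case-minus-control differences: zero differences discarded (classical
convention, the default of the mainstream packages this analysis emulates),
mid-ranks for ties, exact two-sided p by full enumeration of sign
assignments (via dynamic programming, identical to 2ⁿ enumeration) for ≤ 15
nonzero pairs, otherwise a normal approximation with tie and continuity
corrections. Categorical variables use Fisher's exact test with the
two-sided point-probability convention (sum of hypergeometric probabilities
≤ the observed one, relative tolerance 1e-7).

The significance level is Bonferroni-adjusted to α/m with m = 12 — the 5
clinical plus 7 texture comparisons of the univariate table — giving
0.05/12 ≈ 0.00417. m is configurable.

Group summaries are medians with interquartile ranges; quartiles use linear
interpolation (numpy default).

## Conditional logistic regression

For 1:1 pairs the conditional likelihood
`∏ₖ exp(x_case,k·β) / (exp(x_case,k·β) + exp(x_ctrl,k·β))` is a no-intercept
logistic likelihood on within-pair covariate differences with all responses
1. It is maximized by Newton–Raphson with step halving on an internally
standardized scale (coefficients and covariance exactly back-transformed, so
estimates stay on the raw covariate scale). Convergence: max |score| < 1e-8
or relative log-likelihood change < 1e-10, ≤ 50 iterations. Wald SEs from
the observed information; 95% CIs as β ± 1.96·SE, reported on both the
coefficient and the odds-ratio scale (some published tables label
coefficient-scale intervals as OR-scale; emitting both avoids guessing).

Degenerate cases: a covariate with no within-pair variation gets coefficient
0 with infinite SE and is flagged; complete/quasi-complete separation
(standardized coefficient drifting past 50, or every pair probability
within 1e-6 of 1) sets `separation_detected` and suppresses point estimates.
Pairs with any missing covariate are dropped (pairwise deletion; no
imputation), with `n_pairs_used` recording the loss.

## ROC analysis and cutoff validation

Positivity is strict (`score > t`), matching the "> 7.141" form in which
such cutoffs are reported; the threshold is reported as the largest observed
score classified negative, with the midpoint to the next observed score
also available. The AUC is the Mann–Whitney statistic with ties counted ½
(equal to the trapezoidal area under the empirical curve); its 95% CI uses
DeLong's variance estimate. The optimal cutoff maximizes Youden
J = sens + spec − 1, which is equivalent to maximizing the perpendicular
distance J/√2 from the chance diagonal; ties break toward higher
specificity, then lower threshold. Proportion CIs (sens/spec/PPV/NPV) are
Wald intervals, configurable in principle but kept simple deliberately.

The validation stage receives only the serialized cutoff, never the
validation scores during selection — freezing is structural, not by
convention.

Two conflicting published value sets exist for the entropy ROC this pipeline
emulates (AUC 0.770, sens 75.6%, spec 80.5% in one place; AUC 0.768, sens
77.5%, spec 76.2% in another, at the same cutoff). The pipeline does not
adjudicate: both variants are carried as data in `roc_summary.json` under
`reference_variants` with an explicit discrepancy flag.

## Synthetic data generator

**Images.** A slice is fat baseline (stored value 920) plus a Gaussian
random field: white noise smoothed with a Gaussian kernel (σ = 2 px) and
rescaled to the target marginal SD, giving tunable spatial correlation with
one dial. Controls get marginal SD 15; the occult group's marginal SD is
raised to 24 by adding spatially *uncorrelated* excess noise, which
simultaneously raises SD and entropy and dilutes the lag-1 co-occurrence
correlation — the three directions observed in real occult-carcinomatosis
omenta — plus a Poisson(3) number of small bright nodules (radius 2 px,
+60 gray values) standing in for micro-deposits and contributing positive
skewness. The two dials (excess noise vs. nodules) can be moved
independently so tests can isolate features. SD levels 15/24 mirror the
reported group medians (14.6/23.8).

Each patient additionally draws a unit-mean lognormal factor (CV 0.15)
multiplying their noise level: real cohorts are not homogeneous within a
group, and the reported entropy IQRs (~0.3 bits wide) back-solve to roughly
a 15% spread of the underlying noise SD. Without this dispersion the groups
would separate perfectly, which no real cohort does.

ROIs are random star-shaped polygons (simple by construction) around the
image center, regenerated larger until they rasterize to ≥ 157 pixels (the
smallest ROI in the emulated study's range). Pixel units are abstract; no
pixel spacing is modelled (the published area-vs-pixel-count figures are
mutually inconsistent, so no spacing can be inferred).

**Cohorts.** 41 test and 10 validation pairs by default. Both members of a
pair share a cT/cN stratum; at the default sizes the strata counts replicate
the emulated study's staging distribution exactly, otherwise strata are
sampled proportionally. Clinical covariates (age, sex, BMI, ascites, grade)
are drawn from identical margins for both groups — the matched design's
null clinical effect — so any clinical "significance" downstream is a false
positive by construction, which the calibration tests exploit.

**Feature-level simulator.** For statistics-stage tests the seven features
can be drawn directly from group-specific multivariate normals: control
means and SDs on the scale of the emulated study's control medians and IQRs,
case shifts defaulting to the reported median gaps (entropy +0.3, SD +9.2,
average +29, paper-scale correlation −0.001, …), and a one-factor
correlation structure (all features load on a common "heterogeneity" factor;
entropy and SD at 0.85, correlation variants at −0.7) reflecting that all
seven are functionals of the same ROI. An explicit correlation matrix can be
supplied instead and is rejected if not positive definite. With zero effect
the generator is an exact null for every downstream test.

**Randomness.** One global seed expands into per-patient substreams through
`numpy.random.SeedSequence` spawn keys (counter-based), so any patient's
data is reproducible independently of generation order, and the entire
pipeline is a pure function of (config, seed) — byte-identical outputs on
rerun.

**What the generator does not emulate.** Anatomy (vessels, bowel, organ
boundaries), contrast-phase and scanner effects, 3D structure, reader
variability in ROI placement, and the heavy-tailed/skewed marginals of real
CT texture. Passing tests therefore demonstrate that the *analysis machinery*
is correct and calibrated under a controlled model of the study conditions —
not that the biological effect itself is reproducible from this repository,
which would require the original images.

## Problem sizes

Default analyses use the full simulated design (41 + 10 pairs, 128×128
images). Calibration studies use 200 replicates for coefficient recovery,
500 for familywise-error measurement, and 200 image pairs for
effect-direction checks; oracle-equivalence suites run on images ≤ 8×8 and
samples ≤ 15 where exhaustive enumeration is feasible.

## Known limitations

* With image-backed defaults the group contrast implied by the reported SD
  medians (15 vs 24) separates the cohorts almost perfectly (AUC ≈ 0.99),
  more strongly than the reported entropy gap alone (AUC 0.77); real data
  presumably decouple SD and entropy more than a Gaussian field can. The
  feature-level simulator reproduces the reported overlap directly.
* A four-covariate conditional logit on strongly co-determined features at
  41 pairs frequently separates or yields unstable coefficients; the
  pipeline reports this honestly (the published fit shows the same
  instability as enormous CIs).
* Wald proportion CIs are anti-conservative at n = 10; they are retained as
  the convention of the era's clinical software.
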
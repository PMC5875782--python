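"""Univariate statistics and conditional logistic regression for 1:1 matched cohorts.

The study design is a matched case-control comparison: each occult-carcinomatosis
patient is paired with a stage-matched control.  Continuous variables are compared
with the Wilcoxon signed-rank test on within-pair differences, categorical ones
with Fisher's exact test, with a Bonferroni-adjusted significance level over the
full set of comparisons.  The multivariable model is conditional logistic
regression, which for 1:1 pairs reduces to a no-intercept logistic likelihood on
within-pair covariate differences with all responses equal to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CLogitFit",
    "wilcoxon_signed_rank",
    "fisher_exact_2x2",
    "bonferroni_adjust",
    "clogit_from_differences",
    "clogit_fit",
    "univariate_table",
    "pair_differences",
    "TEXTURE_FEATURES",
    "CONTINUOUS_CLINICAL",
    "CATEGORICAL_CLINICAL",
]

#: feature columns compared in the univariate table (7 texture features)
TEXTURE_FEATURES = (
    "average",
    "contrast",
    "correlation",
    "entropy",
    "kurtosis",
    "skewness",
    "std_dev",
)
CONTINUOUS_CLINICAL = ("age", "bmi")
CATEGORICAL_CLINICAL = ("sex", "ascites", "grade")

#: exact-enumeration limit for the signed-rank test (2^n sign vectors)
_EXACT_N = 15


@dataclass(frozen=True)
class TestResult:
    """Outcome of one univariate hypothesis test."""

    variable: str
    test: str  # "fisher_exact" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    adjusted_alpha: float = 0.05
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < self.adjusted_alpha


def wilcoxon_signed_rank(
    case_values: Sequence[float],
    control_values: Sequence[float],
    adjusted_alpha: float = 0.05,
    variable: str = "",
) -> TestResult:
    """Paired Wilcoxon signed-rank test (two-sided) on case - control differences.

    Zero differences are discarded (classical convention); tied absolute
    differences get mid-ranks.  The p-value is exact (full enumeration of the
    2^n sign assignments, computed by dynamic programming) when at most 15
    nonzero differences remain, otherwise a normal approximation with tie and
    continuity corrections is used.  The statistic is W+, the positive rank sum.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.shape != control.shape:
        raise ValueError("paired sequences must have equal length")
    d = case - control
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(variable, "wilcoxon_signed_rank", 0.0, 1.0, adjusted_alpha, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= _EXACT_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        if sigma2 <= 0:
            return TestResult(variable, "wilcoxon_signed_rank", w_plus, 1.0, adjusted_alpha, degenerate=True)
        dev = w_plus - mu
        # continuity correction shrinks |dev| by 0.5
        z = (dev - 0.5 * np.sign(dev)) / math.sqrt(sigma2) if dev != 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(variable, "wilcoxon_signed_rank", w_plus, float(p), adjusted_alpha)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments, mid-ranks allowed.

    Ranks are doubled so mid-ranks (.5) become integers; the distribution of
    2*W+ is built by polynomial convolution, equivalent to enumerating all
    2^n sign vectors.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dp = np.zeros(total + 1, dtype=float)
    dp[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dp)
        shifted[r:] = dp[: total + 1 - r]
        dp = dp + shifted
    dp /= dp.sum()
    w2 = int(round(2 * w_plus))
    p_le = dp[: w2 + 1].sum()
    p_ge = dp[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def fisher_exact_2x2(
    table: Sequence[Sequence[int]],
    adjusted_alpha: float = 0.05,
    variable: str = "",
) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The two-sided p-value is the sum of hypergeometric point probabilities not
    exceeding the observed table's probability (point-probability method), with
    a 1e-7 relative tolerance in the comparison.  The statistic reported is the
    sample odds ratio (ad/bc, inf when bc == 0).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or (t < 0).any():
            raise ValueError("counts must be non-negative integers")
        t = np.round(t).astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = sps.hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(variable, "fisher_exact", odds, min(1.0, p), adjusted_alpha)


def bonferroni_adjust(alpha: float = 0.05, m: int = 12) -> float:
    """Bonferroni-adjusted per-comparison significance level alpha / m.

    The pipeline default m = 12 covers the 5 clinical + 7 texture comparisons
    of the univariate table, giving 0.05 / 12 = 0.004167.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


# --------------------------------------------------------------------------
# conditional logistic regression (1:1 matching)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CLogitFit:
    """Conditional logistic regression fit for 1:1 matched pairs."""

    covariates: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    converged: bool
    separation_detected: bool
    n_pairs_used: int
    log_likelihood: float
    zero_information: tuple[str, ...] = field(default=())

    @property
    def odds_ratio(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef)

    @property
    def or_ci_low(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.ci_low)

    @property
    def or_ci_high(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.ci_high)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "z": self.z,
                "p_value": self.p_values,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "odds_ratio": self.odds_ratio,
                "or_ci_low": self.or_ci_low,
                "or_ci_high": self.or_ci_high,
            },
            index=list(self.covariates),
        )


def clogit_from_differences(
    D: np.ndarray,
    covariates: Sequence[str],
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    separation_bound: float = 50.0,
) -> CLogitFit:
    """Maximize the 1:1 conditional likelihood given case-minus-control differences.

    The conditional likelihood  prod_k  e^{x_case,k b} / (e^{x_case,k b} + e^{x_ctrl,k b})
    equals a no-intercept logistic likelihood on the difference rows of ``D``
    with all responses 1; it is maximized by Newton-Raphson on an internally
    standardized scale and back-transformed.  Wald SEs come from the observed
    information.  Covariates whose differences are all zero carry no
    information: their coefficient is 0 with infinite SE.  Monotone likelihoods
    (complete/quasi-complete separation, detected when a standardized
    coefficient exceeds ``separation_bound``) yield ``separation_detected`` and
    NaN estimates.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    k, p = D.shape
    covariates = tuple(covariates)
    if len(covariates) != p:
        raise ValueError("covariate name count must match difference columns")
    if k == 0:
        raise ValueError("no pairs")

    scale = D.std(axis=0, ddof=0)
    informative = scale > 0
    zero_info = tuple(name for name, ok in zip(covariates, informative) if not ok)
    Ds = D[:, informative] / scale[informative]
    q = Ds.shape[1]

    beta_s = np.zeros(q)
    separation = False
    converged = False
    ll = -k * math.log(2.0)
    if q > 0:
        for _ in range(max_iter):
            eta = Ds @ beta_s
            pk = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            score = Ds.T @ (1.0 - pk)
            w = pk * (1.0 - pk)
            H = (Ds * w[:, None]).T @ Ds
            if np.max(np.abs(score)) < score_tol:
                converged = True
                break
            try:
                step = np.linalg.solve(H, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, score, rcond=None)[0]
            # halve steps that do not improve the log-likelihood
            new_beta = beta_s + step
            new_ll = float(-np.sum(np.logaddexp(0.0, -(Ds @ new_beta))))
            halvings = 0
            while new_ll < ll and halvings < 20:
                step /= 2.0
                new_beta = beta_s + step
                new_ll = float(-np.sum(np.logaddexp(0.0, -(Ds @ new_beta))))
                halvings += 1
            if np.max(np.abs(new_beta)) > separation_bound:
                separation = True
                break
            rel = abs(new_ll - ll) / max(1.0, abs(ll))
            beta_s, ll = new_beta, new_ll
            if rel < ll_tol:
                converged = True
                break
        # a monotone likelihood drifts toward a perfect fit: every pair
        # probability ~1 means complete/quasi-complete separation
        if not separation and q > 0:
            pk = 1.0 / (1.0 + np.exp(-np.clip(Ds @ beta_s, -700, 700)))
            if pk.min() > 1.0 - 1e-6:
                separation = True

    coef = np.full(p, np.nan)
    se = np.full(p, np.nan)
    if separation:
        converged = False
    else:
        coef[:] = 0.0
        se[:] = np.inf
        if q > 0:
            eta = Ds @ beta_s
            pk = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            w = pk * (1.0 - pk)
            H = (Ds * w[:, None]).T @ Ds
            try:
                cov_s = np.linalg.inv(H)
                se_s = np.sqrt(np.diag(cov_s))
            except np.linalg.LinAlgError:
                se_s = np.full(q, np.inf)
            coef[informative] = beta_s / scale[informative]
            se[informative] = se_s / scale[informative]

    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se
    z = np.where(np.isinf(se), 0.0, z)
    p_vals = 2.0 * sps.norm.sf(np.abs(z))
    p_vals = np.where(np.isnan(coef), np.nan, np.where(np.isinf(se), 1.0, p_vals))
    ci_low = coef - 1.96 * se
    ci_high = coef + 1.96 * se
    return CLogitFit(
        covariates=covariates,
        coef=coef,
        se=se,
        z=np.where(np.isnan(coef), np.nan, z),
        p_values=p_vals,
        ci_low=ci_low,
        ci_high=ci_high,
        converged=converged and not separation,
        separation_detected=separation,
        n_pairs_used=k,
        log_likelihood=ll,
        zero_information=zero_info,
    )


def pair_differences(cohort: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, int]:
    """Case-minus-control covariate differences per pair.

    Pairs with any missing covariate value are dropped (pairwise deletion at
    the pair level); the number of pairs retained is returned alongside.
    """
    need = set(covariates) - set(cohort.columns)
    if need:
        raise KeyError(f"missing covariate column(s): {sorted(need)}")
    cases = cohort[cohort["group"] == "occult"].set_index("pair_id")
    ctrls = cohort[cohort["group"] == "control"].set_index("pair_id")
    common = cases.index.intersection(ctrls.index)
    diffs = cases.loc[common, list(covariates)].to_numpy(dtype=float) - ctrls.loc[
        common, list(covariates)
    ].to_numpy(dtype=float)
    keep = ~np.isnan(diffs).any(axis=1)
    return diffs[keep], int(keep.sum())


def clogit_fit(cohort: pd.DataFrame, covariates: Sequence[str], **kwargs) -> CLogitFit:
    """Conditional logistic regression of occult status on covariates in a matched cohort."""
    D, n_used = pair_differences(cohort, covariates)
    if n_used == 0:
        raise ValueError("no complete pairs with all covariates observed")
    fit = clogit_from_differences(D, covariates, **kwargs)
    return fit


# --------------------------------------------------------------------------
# univariate comparison table
# --------------------------------------------------------------------------


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    med = float(np.quantile(values, 0.5))
    q1 = float(np.quantile(values, 0.25))
    q3 = float(np.quantile(values, 0.75))
    return med, q1, q3


def univariate_table(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    m: int = 12,
    correlation_column: str = "correlation_paper_scale",
) -> pd.DataFrame:
    """Univariate comparison of clinical and texture features between matched groups.

    Continuous variables (age, BMI, 7 texture features) are summarized by
    median and interquartile range per group (quartiles by linear
    interpolation) and compared by paired Wilcoxon; categorical variables
    (sex, ascites, grade) by counts and Fisher's exact test.  All p-values are
    judged against the Bonferroni level ``alpha / m``.
    """
    adj = bonferroni_adjust(alpha, m)
    cases = cohort[cohort["group"] == "occult"].sort_values("pair_id")
    ctrls = cohort[cohort["group"] == "control"].sort_values("pair_id")
    if len(cases) != len(ctrls) or len(cases) == 0:
        raise ValueError("cohort must contain matched occult/control pairs")

    rows = []
    col_map = {name: name for name in CONTINUOUS_CLINICAL + TEXTURE_FEATURES}
    col_map["correlation"] = correlation_column
    for var in CONTINUOUS_CLINICAL + TEXTURE_FEATURES:
        col = col_map[var]
        if col not in cohort.columns:
            raise KeyError(f"missing feature column: {col}")
        cv = cases[col].to_numpy(dtype=float)
        kv = ctrls[col].to_numpy(dtype=float)
        res = wilcoxon_signed_rank(cv, kv, adjusted_alpha=adj, variable=var)
        m_c, q1_c, q3_c = _median_iqr(cv)
        m_k, q1_k, q3_k = _median_iqr(kv)
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "test": res.test,
                "occult_median": m_c,
                "occult_q1": q1_c,
                "occult_q3": q3_c,
                "control_median": m_k,
                "control_q1": q1_k,
                "control_q3": q3_k,
                "occult_count": np.nan,
                "control_count": np.nan,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "adjusted_alpha": adj,
                "significant": res.significant,
            }
        )

    cat_positive = {"sex": "M", "ascites": "present", "grade": "PD-SRC"}
    for var in CATEGORICAL_CLINICAL:
        if var not in cohort.columns:
            raise KeyError(f"missing feature column: {var}")
        pos = cat_positive[var]
        a = int((cases[var] == pos).sum())
        b = int((cases[var] != pos).sum())
        c = int((ctrls[var] == pos).sum())
        d = int((ctrls[var] != pos).sum())
        res = fisher_exact_2x2([[a, c], [b, d]], adjusted_alpha=adj, variable=var)
        rows.append(
            {
                "variable": var,
                "type": "categorical",
                "test": res.test,
                "occult_median": np.nan,
                "occult_q1": np.nan,
                "occult_q3": np.nan,
                "control_median": np.nan,
                "control_q1": np.nan,
                "control_q3": np.nan,
                "occult_count": a,
                "control_count": c,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "adjusted_alpha": adj,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
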
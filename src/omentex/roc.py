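"""ROC analysis, optimal-cutoff selection and frozen-cutoff validation.

The diagnostic score (entropy by default) is evaluated on the test cohort:
the empirical ROC curve is built over all distinct thresholds with a strict
``score > t`` positivity rule, the AUC is the Mann-Whitney statistic (ties
count 1/2, equal to the trapezoidal area) with a DeLong 95% CI, and the
operating point furthest from the chance diagonal — equivalently the point
of maximal Youden J = sensitivity + specificity - 1 — defines the cutoff.
The cutoff is then applied, frozen, to the validation cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCCurve",
    "CutoffResult",
    "ConfusionTable",
    "roc_curve",
    "optimal_cutoff",
    "apply_cutoff",
    "REFERENCE_ROC_VARIANTS",
]

#: The reference study reports two conflicting value sets for the entropy ROC
#: on its test cohort (body text vs. its summary table); both are carried as
#: data so downstream reports can flag the discrepancy instead of silently
#: picking one.
REFERENCE_ROC_VARIANTS = {
    "text": {
        "auc": 0.770,
        "auc_ci": (0.664, 0.856),
        "cutoff": 7.141,
        "sensitivity_pct": 75.6,
        "specificity_pct": 80.5,
    },
    "table": {
        "auc": 0.768,
        "auc_ci": (0.676, 0.861),
        "cutoff": 7.14,
        "sensitivity_pct": 77.5,
        "specificity_pct": 76.2,
    },
}


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve with strict-greater positivity."""

    thresholds: np.ndarray  # sorted, -inf first
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    auc_se: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class CutoffResult:
    """Optimal ROC operating point and its diagnostic performance."""

    threshold: float
    threshold_midpoint: float  # midpoint between threshold and next higher score
    rule: str  # "score > threshold"
    youden_j: float
    distance_from_diagonal: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    confusion: ConfusionTable
    degenerate: bool = False


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Split scores into (case, control) arrays.

    Labels may be booleans, 0/1 integers, or the strings "occult"/"control".
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if y.dtype.kind in "USO":
        known = {"occult": True, "case": True, "control": False}
        try:
            is_case = np.asarray([known[str(v)] for v in y])
        except KeyError as exc:
            raise ValueError(f"unrecognized class label {exc.args[0]!r}") from None
    else:
        is_case = y.astype(bool)
    pos = s[is_case]
    neg = s[~is_case]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, tuple[float, float]]:
    """DeLong standard error and Wald 95% CI for the empirical AUC."""
    m, n = pos.size, neg.size
    # placement values
    v10 = np.empty(m)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n
    v01 = np.empty(n)
    for j, y in enumerate(neg):
        v01[j] = (np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return se, (lo, hi)


def roc_curve(scores: Sequence[float], labels: Sequence) -> ROCCurve:
    """Empirical ROC of a diagnostic score (labels truthy = case).

    Thresholds are all distinct observed scores plus a -inf endpoint; the
    operating point at threshold t uses the strict rule ``score > t``.  AUC is
    the Mann-Whitney U statistic scaled to [0, 1] (ties weighted 1/2); its 95%
    CI comes from DeLong's variance estimate.
    """
    pos, neg = _split(scores, labels)
    thresholds = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg]))])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    auc = float(
        (np.sum(pos[:, None] > neg[None, :]) + 0.5 * np.sum(pos[:, None] == neg[None, :]))
        / (pos.size * neg.size)
    )
    se, ci = _delong_ci(pos, neg, auc)
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci_95=ci,
        auc_se=se,
        n_cases=int(pos.size),
        n_controls=int(neg.size),
    )


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    if n == 0 or math.isnan(p):
        return (float("nan"), float("nan"))
    half = 1.96 * math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def optimal_cutoff(curve: ROCCurve) -> CutoffResult:
    """Operating point furthest from the no-discrimination diagonal.

    Perpendicular distance to the diagonal is J / sqrt(2), so the optimum
    maximizes Youden J; ties are broken toward higher specificity, then lower
    threshold.  The threshold is reported as the largest observed score
    classified negative (strict ``>`` positivity); ``threshold_midpoint``
    additionally gives the midpoint to the next higher observed score.
    Sensitivity/specificity/PPV/NPV carry Wald 95% CIs.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    order = np.lexsort((curve.thresholds, -curve.specificity, -j))
    best = order[0]
    degenerate = bool(np.isclose(j.max(), 0.0))
    t = float(curve.thresholds[best])

    finite = curve.thresholds[np.isfinite(curve.thresholds)]
    higher = finite[finite > t]
    if np.isfinite(t) and higher.size:
        midpoint = (t + float(higher.min())) / 2.0
    else:
        midpoint = t

    sens = float(curve.sensitivity[best])
    spec = float(curve.specificity[best])
    tp = int(round(sens * curve.n_cases))
    fn = curve.n_cases - tp
    tn = int(round(spec * curve.n_controls))
    fp = curve.n_controls - tn
    conf = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return CutoffResult(
        threshold=t,
        threshold_midpoint=midpoint,
        rule="score > threshold",
        youden_j=float(j[best]),
        distance_from_diagonal=float(j[best] / math.sqrt(2.0)),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        sensitivity_ci=_wald_ci(sens, curve.n_cases),
        specificity_ci=_wald_ci(spec, curve.n_controls),
        ppv_ci=_wald_ci(ppv, tp + fp),
        npv_ci=_wald_ci(npv, tn + fn),
        confusion=conf,
        degenerate=degenerate,
    )


def apply_cutoff(
    scores: Sequence[float],
    labels: Sequence,
    threshold: float,
    rule: str = "score > threshold",
) -> tuple[ConfusionTable, dict[str, float]]:
    """Classify scores against a frozen threshold and tabulate performance.

    Positivity is strict: ``score > threshold``.  Returns the confusion table
    and a metric dict (sensitivity, specificity, ppv, npv as proportions, each
    with a Wald 95% CI).  Ratios with empty denominators are NaN, never 0.
    """
    if rule != "score > threshold":
        raise ValueError(f"unsupported positivity rule {rule!r}")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pos, neg = _split(scores, labels)
    tp = int((pos > threshold).sum())
    fn = int(pos.size - tp)
    fp = int((neg > threshold).sum())
    tn = int(neg.size - fp)
    conf = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    metrics = {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "sensitivity_ci": _wald_ci(sens, tp + fn),
        "specificity_ci": _wald_ci(spec, tn + fp),
        "ppv_ci": _wald_ci(ppv, tp + fp),
        "npv_ci": _wald_ci(npv, tn + fn),
    }
    return conf, metrics
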
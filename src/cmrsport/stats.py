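"""ROC diagnostics and covariate-adjusted group comparison.

The ROC machinery follows the reporting conventions of diagnostic CMR
studies: candidate thresholds are the midpoints between adjacent
distinct index values (plus infinite sentinels), classification is
strictly greater-than (positive = HCM), the AUC is the trapezoidal area
(equal to the Mann-Whitney concordance probability with half credit for
ties), and the reported cut-off maximizes the proportion of subjects
correctly classified. Paired AUCs on the same subjects are compared
with DeLong's structural-components test. Group comparisons adjust for
age and heart rate by least-squares regression within strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm, rankdata
import statsmodels.api as sm

from .core import ValidationError


@dataclass
class ConfusionMetrics:
    """Percent metrics from a 2x2 confusion table; ``None`` marks a
    metric whose denominator is zero (undefined, not 0)."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    correctly_classified: float | None
    undefined: tuple[str, ...]


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy in percent.

    Values are unrounded; rounding (nearest integer for prose-style
    PPV/NPV, one decimal for tables) belongs to the reporting layer.
    """
    counts = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    for name, c in counts.items():
        if c < 0 or int(c) != c:
            raise ValidationError(f"{name} must be a non-negative integer")

    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    metrics = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "correctly_classified": ratio(tp + tn, tp + fp + fn + tn),
    }
    undefined = tuple(k for k, v in metrics.items() if v is None)
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn, undefined=undefined, **metrics)


@dataclass
class ROCReport:
    """ROC curve of one index with the accuracy-maximizing cut-off."""

    index_name: str
    thresholds: np.ndarray  # ascending, with -inf/+inf sentinels
    sensitivity: np.ndarray  # %, non-increasing along thresholds
    specificity: np.ndarray  # %, non-decreasing along thresholds
    auc: float
    tp: np.ndarray = field(repr=False, default=None)
    fp: np.ndarray = field(repr=False, default=None)
    fn: np.ndarray = field(repr=False, default=None)
    tn: np.ndarray = field(repr=False, default=None)
    optimal_threshold: float | None = None
    optimum: ConfusionMetrics | None = None


def _check_binary(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValidationError("values and labels must be matching 1-D arrays")
    if np.isnan(values).any():
        raise ValidationError("missing index values are not allowed")
    if labels.all() or not labels.any():
        raise ValidationError("both classes must be present")
    return values, labels


def roc_curve(values, labels, index_name: str = "") -> ROCReport:
    """ROC curve with strict > classification, positive = HCM.

    Thresholds are midpoints between adjacent distinct values plus
    -inf/+inf sentinels; the AUC is trapezoidal.
    """
    values, labels = _check_binary(np.asarray(values), np.asarray(labels))
    distinct = np.unique(values)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])

    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    n_pos, n_neg = pos.size, neg.size
    # predicted positive iff value > t
    tp = n_pos - np.searchsorted(pos, thresholds, side="right")
    fp = n_neg - np.searchsorted(neg, thresholds, side="right")
    fn = n_pos - tp
    tn = n_neg - fp

    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCReport(
        index_name=index_name,
        thresholds=thresholds,
        sensitivity=100.0 * tpr,
        specificity=100.0 * tn / n_neg,
        auc=auc,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def optimal_cutoff(report: ROCReport) -> ROCReport:
    """Fill in the threshold maximizing correct classification.

    Ties are broken toward the smallest threshold, i.e. the more
    sensitive operating point.
    """
    if report.tp is None:
        raise ValidationError("ROC report lacks confusion-count arrays")
    total = report.tp + report.fp + report.fn + report.tn
    accuracy = (report.tp + report.tn) / total
    best = int(np.argmax(accuracy))  # first maximum = smallest threshold
    optimum = confusion_metrics(
        int(report.tp[best]), int(report.fp[best]), int(report.fn[best]), int(report.tn[best])
    )
    return replace(report, optimal_threshold=float(report.thresholds[best]), optimum=optimum)


def roc_with_cutoff(values, labels, index_name: str = "") -> ROCReport:
    """Convenience: ROC curve plus the accuracy-maximizing cut-off."""
    return optimal_cutoff(roc_curve(values, labels, index_name))


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    auc_difference: float
    variance: float  # estimated variance of the AUC difference
    z: float
    p_value: float


def _delong_components(values: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-subject structural components (positives, negatives)."""
    pos = values[labels]
    neg = values[~labels]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def delong_compare(values_a, values_b, labels) -> DeLongComparison:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both indices must be measured on the same subjects, in the same
    order; positive = HCM.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired index vectors must have equal length")
    a, lab = _check_binary(a, np.asarray(labels))
    b, _ = _check_binary(b, np.asarray(labels))

    auc_a, v10_a, v01_a = _delong_components(a, lab)
    auc_b, v10_b, v01_b = _delong_components(b, lab)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0 or not math.isfinite(var):
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if diff == 0 else 2.0 * float(norm.sf(abs(z)))
    return DeLongComparison(
        auc_a=auc_a, auc_b=auc_b, auc_difference=diff, variance=float(var), z=z, p_value=min(p, 1.0)
    )


@dataclass
class GroupComparison:
    """Covariate-adjusted difference between two groups in one stratum."""

    outcome: str
    groups: tuple[str, str]  # difference = second minus first
    stratum: str
    estimate: float
    standard_error: float
    p_value: float
    covariates: tuple[str, ...]
    n: int


def adjusted_group_compare(
    outcome,
    group,
    age,
    heart_rate,
    strata=None,
    outcome_name: str = "outcome",
) -> list[GroupComparison]:
    """Least-squares group comparison adjusted for age and heart rate.

    Within each stratum the outcome is regressed on a group indicator
    plus age and heart rate; the reported difference is the indicator
    coefficient (second group level minus first, levels sorted) with
    its t-test p-value. Each stratum must contain exactly two group
    levels (pairwise comparisons).
    """
    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    age = np.asarray(age, dtype=float)
    heart_rate = np.asarray(heart_rate, dtype=float)
    strata = np.asarray(strata) if strata is not None else np.full(outcome.shape, "all")
    if not (outcome.shape == group.shape == age.shape == heart_rate.shape == strata.shape):
        raise ValidationError("all inputs must have matching lengths")

    results = []
    for stratum in sorted(np.unique(strata).tolist()):
        sel = strata == stratum
        levels = sorted(np.unique(group[sel]).tolist())
        if len(levels) != 2:
            raise ValidationError(
                f"stratum {stratum!r} has {len(levels)} group level(s); pairwise comparison needs 2"
            )
        indicator = (group[sel] == levels[1]).astype(float)
        design = sm.add_constant(
            np.column_stack([indicator, age[sel], heart_rate[sel]]), has_constant="add"
        )
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(f"stratum {stratum!r}: rank-deficient design matrix")
        fit = sm.OLS(outcome[sel], design).fit()
        results.append(
            GroupComparison(
                outcome=outcome_name,
                groups=(str(levels[0]), str(levels[1])),
                stratum=str(stratum),
                estimate=float(fit.params[1]),
                standard_error=float(fit.bse[1]),
                p_value=float(fit.pvalues[1]),
                covariates=("age", "heart_rate"),
                n=int(sel.sum()),
            )
        )
    return results
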
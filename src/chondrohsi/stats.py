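"""Paired comparisons and ROC classification.

The analysis contrasts per-patient healthy and damaged ROI means. Routing
follows the classical recipe: Shapiro-Wilk on the paired differences, then
a paired Student t test when normality is not rejected (p >= 0.05) and the
Wilcoxon signed-rank test otherwise (zero differences dropped, mid-rank
ties). Indices that separate the classes (p < 0.05) are carried into a ROC
analysis with a fixed orientation — higher score predicts damaged, never
auto-flipped, which is what lets an index whose damaged values run *lower*
(the tissue water index) report an AUC below 0.5. Decisions use the strict
rule "predict damaged when score > threshold". The AUC is computed by the
trapezoid rule and coincides with the tie-corrected Mann-Whitney statistic
U/(n_pos * n_neg) with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, InsufficientDataError
from .roi import INDEX_COLUMNS, paired_view

POSITIVE_CLASS = "damaged"
NEGATIVE_CLASS = "healthy"


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of the normality-routed paired comparison."""

    test_used: str  # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    normality_p: float
    n_pairs: int


@dataclass(frozen=True)
class OperatingPoint:
    """Sensitivity/specificity of one fixed decision threshold."""

    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ROCResult:
    """Full threshold sweep for one score.

    ``thresholds`` runs from -inf through every unique score to +inf; with
    the strict-greater decision rule the curve starts at (fpr, tpr) = (1, 1)
    and ends at (0, 0) as the threshold increases.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    positive_class: str = POSITIVE_CLASS
    orientation: str = "higher-score-predicts-positive"


def _split_classes(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == POSITIVE_CLASS]
    neg = scores[labels == NEGATIVE_CLASS]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("scores must be finite")
    return pos, neg


def paired_compare(
    healthy: np.ndarray,
    damaged: np.ndarray,
    alpha_normality: float = 0.05,
) -> PairedTestResult:
    """Normality-routed two-sided paired test on damaged - healthy.

    Shapiro-Wilk is applied to the per-patient differences; if its p-value
    is >= ``alpha_normality`` the paired t test is used, otherwise the
    Wilcoxon signed-rank test with zero differences dropped.
    """
    healthy = np.asarray(healthy, dtype=float)
    damaged = np.asarray(damaged, dtype=float)
    if healthy.shape != damaged.shape or healthy.ndim != 1:
        raise ValueError("healthy and damaged must be equal-length 1-D vectors")
    n = healthy.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {n}")
    if not (np.all(np.isfinite(healthy)) and np.all(np.isfinite(damaged))):
        raise ValueError("inputs must be finite")
    diffs = damaged - healthy
    if np.all(diffs == 0):
        raise DegenerateDataError("all paired differences are zero")
    normality_p = float(sps.shapiro(diffs).pvalue)
    if normality_p >= alpha_normality:
        res = sps.ttest_rel(damaged, healthy)
        return PairedTestResult(
            "paired_t", float(res.statistic), float(res.pvalue), normality_p, n
        )
    res = sps.wilcoxon(diffs, zero_method="wilcox", correction=False,
                       alternative="two-sided")
    return PairedTestResult(
        "wilcoxon_signed_rank",
        float(res.statistic),
        float(res.pvalue),
        normality_p,
        n,
    )


def operating_point(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> OperatingPoint:
    """Counts and rates of the strict rule ``predict damaged if score > t``.

    A score exactly equal to the threshold is classified negative.
    """
    pos, neg = _split_classes(scores, labels)
    tp = int(np.sum(pos > threshold))
    fn = pos.size - tp
    fp = int(np.sum(neg > threshold))
    tn = neg.size - fp
    return OperatingPoint(
        threshold=float(threshold),
        sensitivity=tp / pos.size,
        specificity=tn / neg.size,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Threshold sweep over all unique scores, with -inf/+inf sentinels.

    The positive class is fixed to ``damaged`` and higher scores predict
    positive (no auto-flip). The AUC is the trapezoid area of the (fpr, tpr)
    curve, identical to the tie-corrected Mann-Whitney U/(n_pos*n_neg).
    """
    pos, neg = _split_classes(scores, labels)
    thresholds = np.concatenate(
        ([-np.inf], np.unique(np.concatenate([pos, neg])), [np.inf])
    )
    # strict >: vectorized counts of scores above each threshold
    tpr = (pos[None, :] > thresholds[:, None]).sum(axis=1) / pos.size
    fpr = (neg[None, :] > thresholds[:, None]).sum(axis=1) / neg.size
    # integrate from (0,0) to (1,1): reverse the sweep (fpr is non-increasing)
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr.astype(float),
        fpr=fpr.astype(float),
        auc=auc,
        n_pos=pos.size,
        n_neg=neg.size,
    )


def auc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force AUC: fraction of (damaged, healthy) pairs with the
    damaged score higher, ties counted 1/2. Oracle for :func:`roc_curve`."""
    pos, neg = _split_classes(scores, labels)
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def acceptable_threshold(
    roc: ROCResult, min_sens: float = 0.80, min_spec: float = 0.80
) -> OperatingPoint | None:
    """Best clinically acceptable operating point, or ``None``.

    Among finite swept thresholds with sensitivity and specificity both at
    least the given minima, returns the one maximizing Youden's J
    (sens + spec - 1); the lowest qualifying threshold wins ties.
    """
    sens = roc.tpr
    spec = 1.0 - roc.fpr
    ok = (sens >= min_sens) & (spec >= min_spec) & np.isfinite(roc.thresholds)
    if not np.any(ok):
        return None
    j = np.where(ok, sens + spec - 1.0, -np.inf)
    i = int(np.argmax(j))  # argmax takes the first (lowest threshold) on ties
    tp = int(round(sens[i] * roc.n_pos))
    fp = int(round(roc.fpr[i] * roc.n_neg))
    return OperatingPoint(
        threshold=float(roc.thresholds[i]),
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
        tp=tp,
        fp=fp,
        tn=roc.n_neg - fp,
        fn=roc.n_pos - tp,
    )


def screen_parameters(
    table: pd.DataFrame,
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
) -> dict[str, dict]:
    """Paired test for every index; ROC only where the test is significant.

    Mirrors the study design: all candidate parameters get the paired
    comparison, and ROC tables are computed only for those with p < alpha.
    ROC scores are the per-patient class means (n pairs of values).
    Returns ``{index: {"paired": PairedTestResult, "roc": ROCResult | None,
    "acceptable": OperatingPoint | None}}``.
    """
    report: dict[str, dict] = {}
    for index_name in INDEX_COLUMNS:
        healthy, damaged, _ = paired_view(table, index_name)
        paired = paired_compare(healthy, damaged, alpha_normality)
        roc = None
        acceptable = None
        if paired.p_value < alpha:
            scores = np.concatenate([healthy, damaged])
            labels = np.array(
                [NEGATIVE_CLASS] * healthy.size + [POSITIVE_CLASS] * damaged.size
            )
            roc = roc_curve(scores, labels)
            acceptable = acceptable_threshold(roc)
        report[index_name] = {
            "paired": paired,
            "roc": roc,
            "acceptable": acceptable,
        }
    return report
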
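"""ROC/AUC evaluation, DeLong comparisons, cutoff selection and confusion
metrics.

The AUC is the Mann-Whitney pair statistic (ties get half credit), computed
through scikit-learn's trapezoidal ROC. Variances and confidence intervals
use DeLong's structural-components estimator with a normal approximation;
the two-sided DeLong test compares two AUCs either paired (same subjects
scored by two models, covariance included) or unpaired (independent
cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    variance: float
    n_pos: int
    n_neg: int


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    variance_diff: float
    z: float
    p_value: float
    paired: bool


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def _structural_components(scores, y):
    """DeLong placement values V10 (per positive) and V01 (per negative).

    Computed via midranks; the AUC equals the mean of either vector.
    """
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = rankdata(np.concatenate([pos, neg]))  # midranks handle ties
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    return v10, v01


def auc_variance(scores, labels) -> float:
    """DeLong variance of a single AUC."""
    y = _check_labels(labels)
    v10, v01 = _structural_components(scores, y)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, alpha: float = 0.05) -> ROCResult:
    """ROC curve with AUC and a DeLong-normal confidence interval."""
    y = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    var = auc_variance(scores, y)
    zq = norm.ppf(1 - alpha / 2)
    half = zq * np.sqrt(var)
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        variance=float(var),
        n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()),
    )


def delong_test(scores_a, scores_b, labels, paired: bool = True,
                labels_b=None) -> DeLongComparison:
    """Two-sided DeLong test for a difference between two AUCs.

    Paired mode requires both score vectors over the same subjects
    (``labels``). Unpaired mode compares independent cohorts and needs
    ``labels_b`` for the second one.
    """
    y = _check_labels(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if paired:
        if len(scores_a) != len(y) or len(scores_b) != len(y):
            raise ValueError("paired mode requires equally sized score "
                             "vectors over the same subjects")
        va10, va01 = _structural_components(scores_a, y)
        vb10, vb01 = _structural_components(scores_b, y)
        m, n = len(va10), len(va01)
        auc_a, auc_b = float(va10.mean()), float(vb10.mean())
        if m > 1:
            s10 = np.cov(va10, vb10, ddof=1)
        else:
            s10 = np.zeros((2, 2))
        if n > 1:
            s01 = np.cov(va01, vb01, ddof=1)
        else:
            s01 = np.zeros((2, 2))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        yb = _check_labels(labels_b if labels_b is not None else labels)
        auc_a = float(roc_auc_score(y, scores_a))
        auc_b = float(roc_auc_score(yb, scores_b))
        var = auc_variance(scores_a, y) + auc_variance(scores_b, yb)
        paired = False
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = float(min(1.0, 2 * norm.sf(abs(z))))
    return DeLongComparison(auc_a, auc_b, float(var), float(z), p, paired)


def best_accuracy_cutoff(scores, labels) -> float:
    """Cutoff (>= rule) maximizing accuracy; ties go to the lowest cutoff.

    Candidates are the midpoints between adjacent sorted unique scores plus
    two boundary cutoffs (everything positive / everything negative).
    """
    y = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]  # everything scored >= cutoff -> all positive
    candidates += list((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.append(uniq[-1] + 1.0)  # all negative
    best_c, best_acc = None, -1.0
    for c in candidates:
        acc = float(((scores >= c).astype(int) == y).mean())
        if acc > best_acc:  # strictly better keeps the lowest tied cutoff
            best_acc, best_c = acc, c
    return float(best_c)


def confusion_metrics(scores, labels, cutoff: float = 0.58) -> dict:
    """Accuracy, sensitivity, specificity under the >= cutoff convention."""
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=float) >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    return {
        "accuracy": (tp + tn) / len(y) if len(y) else float("nan"),
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }
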
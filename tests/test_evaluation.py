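"""ROC/AUC, DeLong variance and test, cutoff selection, confusion metrics.

The independent oracles: brute-force pair counting for the AUC, an
exhaustive threshold scan for the best-accuracy cutoff, subject bootstrap
for the DeLong variance, and R's pROC (roc.test / ci.auc) for the DeLong
test itself.
"""

import shutil
import subprocess

import numpy as np
import pytest

from slidemil import (best_accuracy_cutoff, confusion_metrics, delong_test,
                      roc_auc)
from slidemil.evaluation import auc_variance


def pair_count_auc(scores, labels):
    """P(score_pos > score_neg) + 0.5 P(tie), by explicit enumeration."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_auc_equals_pair_counting_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(6, 40)
        y = np.zeros(n, int)
        y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if y.min() == y.max():
            continue
        scores = np.round(rng.random(n), 1)    # plenty of ties
        assert roc_auc(scores, y).auc == pytest.approx(
            pair_count_auc(scores, y), abs=1e-12
        )


def test_auc_examples():
    assert roc_auc([0.9, 0.4, 0.8, 0.2], [1, 1, 0, 0]).auc == \
        pytest.approx(0.75)
    assert roc_auc([1, 1, 0, 0], [1, 1, 0, 0]).auc == 1.0


def test_null_auc_near_half():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 2000)
    y[:2] = [0, 1]
    scores = rng.random(2000)
    assert roc_auc(scores, y).auc == pytest.approx(0.5, abs=0.04)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    y = np.r_[np.ones(30, int), np.zeros(40, int)]
    s = rng.random(70)
    base = roc_auc(s, y).auc
    for f in (lambda x: 3 * x + 1, np.exp, lambda x: x ** 3):
        assert roc_auc(f(s), y).auc == pytest.approx(base, abs=1e-12)


def test_roc_curve_monotone():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    res = roc_auc(rng.random(100), y)
    assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()


def test_single_class_labels_rejected():
    with pytest.raises(ValueError, match="class"):
        roc_auc([0.1, 0.2], [1, 1])
    with pytest.raises(ValueError, match="class"):
        delong_test([0.1, 0.2], [0.3, 0.4], [0, 0])


# -- DeLong -----------------------------------------------------------------


def test_identical_scores_give_p_one():
    y = np.r_[np.ones(10, int), np.zeros(10, int)]
    s = np.linspace(0, 1, 20)
    res = delong_test(s, s, y)
    assert res.auc_a == res.auc_b
    assert res.p_value == 1.0 and res.z == 0.0


def test_swapping_models_negates_z_keeps_p():
    rng = np.random.default_rng(4)
    y = np.r_[np.ones(25, int), np.zeros(25, int)]
    a = rng.normal(y, 1.0)
    b = rng.normal(0.5 * y, 1.0)
    r1 = delong_test(a, b, y)
    r2 = delong_test(b, a, y)
    assert r2.z == pytest.approx(-r1.z, abs=1e-12)
    assert r2.p_value == pytest.approx(r1.p_value, abs=1e-12)


def test_delong_variance_matches_bootstrap():
    """DeLong variance of one AUC vs a 2,000-replicate stratified subject
    bootstrap at n=200, within 15% relative error."""
    rng = np.random.default_rng(5)
    y = np.r_[np.ones(100, int), np.zeros(100, int)]
    s = rng.normal(y * 0.7, 1.0)
    var = auc_variance(s, y)
    pos, neg = s[y == 1], s[y == 0]
    reps = []
    for _ in range(2000):
        bp = rng.choice(pos, size=len(pos))
        bn = rng.choice(neg, size=len(neg))
        reps.append(pair_count_auc(np.r_[bp, bn], y))
    boot = np.var(reps, ddof=1)
    assert var == pytest.approx(boot, rel=0.15)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript unavailable")
def test_delong_agrees_with_proc():
    """Paired DeLong p/z and the AUC confidence interval match R pROC."""
    rng = np.random.default_rng(42)
    y = np.r_[np.ones(20, int), np.zeros(20, int)]
    a = rng.normal(y * 0.8, 1)
    b = rng.normal(y * 0.4, 1)
    res = delong_test(a, b, y, paired=True)
    roc = roc_auc(a, y)
    code = (
        'suppressMessages(library(pROC));'
        f'y<-c({",".join(map(str, y))});'
        f'a<-c({",".join(map(str, a))});'
        f'b<-c({",".join(map(str, b))});'
        'ra<-roc(y,a,quiet=TRUE,direction="<");'
        'rb<-roc(y,b,quiet=TRUE,direction="<");'
        't<-roc.test(ra,rb,method="delong",paired=TRUE);'
        'ci<-ci.auc(ra,method="delong");'
        'cat(sprintf("%.12f,%.12f,%.12f,%.12f",'
        't$p.value,t$statistic,ci[1],ci[3]))'
    )
    out = subprocess.run(["Rscript", "-e", code], capture_output=True,
                         text=True, check=True)
    p_r, z_r, lo_r, hi_r = map(float, out.stdout.strip().split(","))
    assert res.p_value == pytest.approx(p_r, abs=1e-9)
    assert res.z == pytest.approx(z_r, abs=1e-9)
    assert roc.ci_low == pytest.approx(lo_r, abs=1e-9)
    assert roc.ci_high == pytest.approx(hi_r, abs=1e-9)


def test_unpaired_mode_compares_independent_cohorts():
    rng = np.random.default_rng(6)
    ya = np.r_[np.ones(30, int), np.zeros(30, int)]
    yb = np.r_[np.ones(25, int), np.zeros(35, int)]
    a = rng.normal(ya, 1.0)
    b = rng.normal(yb, 1.0)
    res = delong_test(a, b, ya, paired=False, labels_b=yb)
    assert 0 <= res.p_value <= 1
    assert res.variance_diff == pytest.approx(
        auc_variance(a, ya) + auc_variance(b, yb)
    )


# -- cutoff and confusion ---------------------------------------------------


def exhaustive_best_accuracy(scores, labels):
    scores = np.asarray(scores, float)
    y = np.asarray(labels)
    uniq = np.unique(scores)
    cands = np.r_[uniq[0] - 1, (uniq[:-1] + uniq[1:]) / 2, uniq[-1] + 1]
    accs = [((scores >= c).astype(int) == y).mean() for c in cands]
    best = max(accs)
    return best, cands[int(np.argmax(accs))]   # argmax -> lowest tied cutoff


def test_best_accuracy_cutoff_examples():
    assert best_accuracy_cutoff([0.1, 0.9], [0, 1]) == pytest.approx(0.5)
    # all scores equal: accuracy is the majority-class rate everywhere;
    # the lowest candidate wins the tie
    cut = best_accuracy_cutoff([0.4, 0.4, 0.4, 0.4], [1, 0, 1, 0])
    assert cut == pytest.approx(-0.6)


def test_best_accuracy_cutoff_matches_exhaustive_scan():
    rng = np.random.default_rng(7)
    for _ in range(500):
        n = rng.integers(4, 50)
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        scores = np.round(rng.random(n), 2)
        cut = best_accuracy_cutoff(scores, y)
        best_acc, best_cut = exhaustive_best_accuracy(scores, y)
        acc = ((scores >= cut).astype(int) == y).mean()
        assert acc == pytest.approx(best_acc, abs=1e-12)
        assert cut == pytest.approx(best_cut, abs=1e-12)


def test_confusion_metrics_hand_counted():
    m = confusion_metrics([0.6, 0.5, 0.7, 0.3], [1, 1, 0, 0], cutoff=0.58)
    assert (m["accuracy"], m["sensitivity"], m["specificity"]) == \
        (0.5, 0.5, 0.5)
    perfect = confusion_metrics([0.9, 0.1], [1, 0], cutoff=0.58)
    assert (perfect["accuracy"], perfect["sensitivity"],
            perfect["specificity"]) == (1.0, 1.0, 1.0)


def test_score_at_cutoff_counts_positive():
    m = confusion_metrics([0.58], [1], cutoff=0.58)
    assert m["tp"] == 1 and m["sensitivity"] == 1.0
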
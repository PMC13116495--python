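"""Seven-metric panel against independent brute-force implementations."""

import numpy as np
import pytest

from ppcsurv import bootstrap_ci, compute_metrics, confusion
from ppcsurv.metrics import METRIC_NAMES


# -- independent oracles ----------------------------------------------------

def oracle_roc_auc(labels, probs):
    """Mann-Whitney statistic with tie correction, by direct pair counting."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (pos.size * neg.size)


def oracle_pr_auc(labels, probs):
    """Step-wise average precision: sum of (delta recall) * precision over
    descending unique score cut-offs."""
    order = np.argsort(-probs, kind="stable")
    y = labels[order]
    p = probs[order]
    n_pos = y.sum()
    ap = 0.0
    tp = fp = 0
    i = 0
    prev_recall = 0.0
    while i < y.size:
        j = i
        while j < y.size and p[j] == p[i]:  # process tied scores as a block
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def oracle_panel(labels, preds, probs):
    tp = np.sum((labels == 1) & (preds == 1))
    fp = np.sum((labels == 0) & (preds == 1))
    fn = np.sum((labels == 1) & (preds == 0))
    tn = np.sum((labels == 0) & (preds == 0))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1p = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    f1n = 2 * npv * spec / (npv + spec) if npv + spec else 0.0
    return {
        "precision": prec,
        "recall": rec,
        "accuracy": (tp + tn) / labels.size,
        "f1_macro": (f1p + f1n) / 2,
        "roc_auc": oracle_roc_auc(labels, probs),
        "pr_auc": oracle_pr_auc(labels, probs),
        "specificity": spec,
    }


# -- tests ------------------------------------------------------------------

def test_confusion_examples():
    assert confusion([1, 0], [1, 0]) == (1, 0, 0, 1)
    assert confusion([1, 1, 0, 0], [0, 0, 1, 1]) == (0, 2, 2, 0)
    with pytest.raises(ValueError):
        confusion([1, 2], [0, 1])
    with pytest.raises(ValueError):
        confusion([1, 0, 1], [0, 1])


def test_confusion_counts_sum_to_n(rng):
    for _ in range(100):
        n = int(rng.integers(2, 50))
        y = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        assert sum(confusion(y, p)) == n


def test_perfect_predictions_score_one(rng):
    y = np.array([0, 1] * 25)
    probs = y.astype(float) * 0.8 + 0.1
    rep = compute_metrics(y, y, probs)
    for m in METRIC_NAMES:
        assert rep[m] == pytest.approx(1.0)


def test_hand_computed_confusion_panel():
    # (TP, FP, FN, TN) = (5, 5, 5, 85)
    y = np.array([1] * 10 + [0] * 90)
    p = np.array([1] * 5 + [0] * 5 + [1] * 5 + [0] * 85)
    rep = compute_metrics(y, p)
    assert rep.precision == pytest.approx(0.5)
    assert rep.recall == pytest.approx(0.5)
    assert rep.specificity == pytest.approx(85 / 90)
    assert rep.accuracy == pytest.approx(0.9)
    assert rep.f1_macro == pytest.approx(0.5 * (0.5 + 85 / 90))


def test_anticorrelated_probabilities_give_auc_below_half(rng):
    y = rng.integers(0, 2, 200)
    probs = 1.0 - (0.6 * y + 0.2 * rng.random(200))
    rep = compute_metrics(y, (probs > 0.5).astype(int), probs)
    assert rep.roc_auc < 0.5


def test_single_class_flags_aucs_undefined():
    y = np.ones(10, dtype=int)
    rep = compute_metrics(y, y, np.linspace(0, 1, 10))
    assert np.isnan(rep.roc_auc) and np.isnan(rep.pr_auc)
    assert rep.recall == 1.0


def test_panel_matches_bruteforce_oracle(rng):
    for _ in range(100):
        n = 200
        y = (rng.random(n) < 0.25).astype(int)
        if y.sum() in (0, n):
            y[:2] = [0, 1]
        probs = np.clip(rng.normal(0.3 + 0.35 * y, 0.2), 0.0, 1.0)
        preds = (probs > rng.uniform(0.2, 0.7)).astype(int)
        rep = compute_metrics(y, preds, probs)
        expected = oracle_panel(y, preds, probs)
        for m in METRIC_NAMES:
            assert rep[m] == pytest.approx(expected[m], abs=1e-9), m


def test_bootstrap_ci_contracts(rng):
    y = np.array([0, 1] * 40)
    probs = np.clip(0.25 + 0.5 * y + rng.normal(0, 0.1, 80), 0, 1)
    preds = (probs > 0.5).astype(int)
    ci = bootstrap_ci(y, preds, probs, n_boot=200, seed=4)
    rep = compute_metrics(y, preds, probs)
    for m in METRIC_NAMES:
        lo, hi = ci[m]
        assert lo <= hi
        assert lo - 1e-12 <= rep[m] <= hi + 1e-12
    assert bootstrap_ci(y, preds, probs, n_boot=200, seed=4) == ci  # determinism
    with pytest.raises(ValueError):
        bootstrap_ci(y, preds, probs, n_boot=50)


def test_bootstrap_perfect_classifier_degenerate_interval(rng):
    y = np.array([0] * 30 + [1] * 30)
    probs = y.astype(float) * 0.9 + 0.05
    ci = bootstrap_ci(y, y.copy(), probs, n_boot=150, seed=1)
    assert ci["accuracy"] == (1.0, 1.0)
    assert ci["roc_auc"] == (1.0, 1.0)
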
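"""Seven-metric evaluation panel with bootstrap confidence intervals.

Metrics: precision, recall (sensitivity), accuracy, F1-macro, ROC-AUC,
PR-AUC and specificity.  ROC-AUC is the Mann-Whitney statistic (trapezoidal
ROC area); PR-AUC uses step-wise interpolation of precision between recall
points (no linear interpolation).  Confidence intervals are percentile
intervals from paired case resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricsReport", "confusion", "compute_metrics", "bootstrap_ci", "evaluate"]

METRIC_NAMES = (
    "precision",
    "recall",
    "accuracy",
    "f1_macro",
    "roc_auc",
    "pr_auc",
    "specificity",
)


def confusion(labels, preds) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) counts for binary labels/predictions."""
    y = np.asarray(labels)
    p = np.asarray(preds)
    if y.shape != p.shape:
        raise ValueError("labels and preds must have equal length")
    for arr, what in ((y, "labels"), (p, "preds")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{what} must be binary (0/1)")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    return tp, fp, fn, tn


def _rank_roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks (tie-aware); low-overhead path used
    inside tight bootstrap loops."""
    from scipy.stats import rankdata

    r = rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return (r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _f1(prec: float, rec: float) -> float:
    return 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0


@dataclass
class MetricsReport:
    """Point estimates (and optional 95% CIs) of the seven-metric panel."""

    precision: float
    recall: float
    accuracy: float
    f1_macro: float
    roc_auc: float
    pr_auc: float
    specificity: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_bootstrap: int = 0
    seed: int | None = None

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in METRIC_NAMES:
            lo, hi = self.ci95.get(m, (np.nan, np.nan))
            rows.append({"metric": m, "value": getattr(self, m), "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


def compute_metrics(labels, preds, probs=None) -> MetricsReport:
    """Point estimates of the seven metrics.

    AUC metrics need ``probs`` and both classes present; otherwise they are
    reported as NaN (flagged undefined) while the threshold metrics are still
    computed.
    """
    tp, fp, fn, tn = confusion(labels, preds)
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    accuracy = (tp + tn) / n if n > 0 else 0.0
    # negative-class precision/recall for the macro average
    npv = tn / (tn + fn) if (tn + fn) > 0 else 0.0
    f1_pos = _f1(precision, recall)
    f1_neg = _f1(npv, specificity)
    f1_macro = 0.5 * (f1_pos + f1_neg)

    y = np.asarray(labels)
    both = np.unique(y).size == 2
    if probs is not None and both:
        roc = float(roc_auc_score(y, np.asarray(probs, dtype=float)))
        pr = float(average_precision_score(y, np.asarray(probs, dtype=float)))
    else:
        roc, pr = float("nan"), float("nan")
    return MetricsReport(precision, recall, accuracy, f1_macro, roc, pr, specificity)


def bootstrap_ci(
    labels,
    preds,
    probs,
    n_boot: int = 1000,
    seed: int = 0,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> dict[str, tuple[float, float]]:
    """Percentile 95% intervals from ``n_boot`` paired case resamples.

    A resample containing a single class is redrawn (at most 100 retries per
    resample) so every AUC is defined.  ``metrics`` restricts the panel when
    only some intervals are needed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    y = np.asarray(labels)
    p = np.asarray(preds)
    pr = np.asarray(probs, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    samples = {m: np.empty(n_boot) for m in metrics}
    for b in range(n_boot):
        for attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        if set(metrics) == {"roc_auc"}:
            samples["roc_auc"][b] = _rank_roc_auc(y[idx], pr[idx])
        else:
            rep = compute_metrics(y[idx], p[idx], pr[idx])
            for m in metrics:
                samples[m][b] = rep[m]
    return {
        m: (float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5)))
        for m, s in samples.items()
    }


def evaluate(
    labels, preds, probs, n_boot: int = 1000, seed: int = 0
) -> MetricsReport:
    """Point estimates plus bootstrap CIs in one report."""
    report = compute_metrics(labels, preds, probs)
    report.ci95 = bootstrap_ci(labels, preds, probs, n_boot=n_boot, seed=seed)
    report.n_bootstrap = n_boot
    report.seed = seed
    return report
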
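"""Evaluation: metrics, chunk-score aggregation, thresholds, comparisons.

Five metrics summarize a model on a fold: AUROC and AUPRC on the raw
scores, plus precision, recall and F1 at an optimal threshold selected on
validation predictions (the threshold maximizing F1). Per-patient note
probabilities are obtained from chunk scores by the max/mean aggregation

    P = (P_max + P_mean * n/2) / (1 + n/2)

over the n chunks of the note. A model is *conclusively better* than
another when it strictly exceeds it on at least three of the five metrics.
Cross-fold results are reported as "mean +/- std" with the sample (n-1)
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

METRIC_NAMES = ("auroc", "f1", "auprc", "precision", "recall")


@dataclass
class MetricReport:
    """The five evaluation metrics for one model on one fold."""

    auroc: float
    auprc: float
    f1: float
    precision: float
    recall: float
    threshold: float = 0.5
    fold: int | None = None

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class FoldSummary:
    """Per-metric mean and sample standard deviation across folds."""

    mean: dict[str, float]
    std: dict[str, float]
    n_folds: int

    def render(self, metric: str) -> str:
        return f"{self.mean[metric]:.4f} ± {self.std[metric]:.4f}"

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {"mean": dict(self.mean), "std": dict(self.std)}


def aggregate_chunk_scores(scores) -> float:
    """Patient-level note probability from n chunk probabilities.

    ``(max + mean * n/2) / (1 + n/2)``; always between the chunk mean and
    the chunk max, and equal to the single probability when n = 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one chunk score")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("chunk scores must lie in [0, 1]")
    n = scores.size
    return float((scores.max() + scores.mean() * n / 2.0) / (1.0 + n / 2.0))


def _prf(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def find_optimal_threshold(scores, labels) -> float:
    """Threshold maximizing F1 over the observed-score midpoints.

    Intended to be computed on validation predictions and then applied to
    test scores. Candidates are the midpoints between consecutive distinct
    scores plus the minimum score (classify-all-positive); ties resolve to
    the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection needs both classes")
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0])
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:
        _, _, f1 = _prf(scores, labels, t)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return float(best_t)


def compute_metrics(scores, labels, threshold: float = 0.5,
                    fold: int | None = None) -> MetricReport:
    """All five metrics; AUROC/AUPRC are threshold-free, the rest use
    ``score >= threshold`` as the positive call."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics need both classes present")
    precision, recall, f1 = _prf(scores, labels, threshold)
    return MetricReport(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        f1=f1, precision=precision, recall=recall,
        threshold=float(threshold), fold=fold,
    )


def conclusively_better(a, b) -> bool:
    """True iff ``a`` strictly exceeds ``b`` in at least three of the five
    metrics. Accepts MetricReports or any mapping with the metric names."""
    def get(x, m):
        return x[m] if isinstance(x, dict) else getattr(x, m)
    wins = sum(get(a, m) > get(b, m) for m in METRIC_NAMES)
    return wins >= 3


def aggregate_folds(reports: list[MetricReport]) -> FoldSummary:
    """Sample mean and (n-1) standard deviation per metric across folds."""
    if len(reports) < 2:
        raise ValueError("need at least two fold reports to aggregate")
    mean, std = {}, {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        mean[m] = float(vals.mean())
        std[m] = float(vals.std(ddof=1))
    return FoldSummary(mean=mean, std=std, n_folds=len(reports))
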
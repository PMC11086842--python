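"""Confusion-count bookkeeping and imbalance-aware evaluation metrics.

Implements the eight classification metrics used throughout the package —
accuracy, sensitivity, specificity, geometric mean (GMean), Matthews
correlation coefficient (MCC), precision, recall and F-Measure — directly
from their confusion-count definitions, plus the rank-based AUC computed via
the Mann-Whitney identity

    AUC = (S_p - n_p(n_p + 1)/2) / (n_p * n_n)

where S_p is the sum of the (ascending, midrank-tied) ranks of the
positive-class scores.  Any metric whose denominator is zero on a degenerate
fold is reported as 0 so that per-fold reports stay total; AUC on
single-class labels is undefined and raises instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

from scipy.stats import rankdata

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts",
           "compute_metrics", "auc_rank", "evaluate_predictions",
           "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. AUC with one class)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts: tp/tn are correct positives/negatives,
    fp/fn the false positives/negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """One row of evaluation results; ``auc`` stays None until scores exist."""

    accuracy: float
    sensitivity: float
    specificity: float
    gmean: float
    mcc: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    counts: ConfusionCounts | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)
             if f.name != "counts"}
        if self.counts is not None:
            d.update(tp=self.counts.tp, tn=self.counts.tn,
                     fp=self.counts.fp, fn=self.counts.fn)
        return d


def _as_binary(v, name: str) -> np.ndarray:
    v = np.asarray(v)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    if not set(np.unique(v).tolist()) <= {0, 1}:
        raise ValueError(f"{name} must contain only 0/1")
    return v.astype(int)


def confusion_counts(labels, predictions) -> ConfusionCounts:
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(p)} predictions")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """All confusion-based metrics; AUC is left unset (needs scores)."""
    if c.total <= 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    f1 = _safe_div(2 * prec * sens, prec + sens)
    return MetricReport(
        accuracy=(tp + tn) / c.total,
        sensitivity=sens,
        specificity=spec,
        gmean=math.sqrt(sens * spec),
        mcc=mcc,
        precision=prec,
        recall=sens,
        f1=f1,
        counts=c,
    )


def auc_rank(labels, scores) -> float:
    """Area under the ROC curve from score ranks (Mann-Whitney identity).

    Scores are ranked ascending with midranks for ties; with S_p the rank sum
    of the positives, AUC = (S_p - n_p(n_p+1)/2)/(n_p n_n).
    """
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores must have equal length")
    n_p = int(y.sum())
    n_n = len(y) - n_p
    if n_p == 0 or n_n == 0:
        raise UndefinedMetricError(
            "AUC is undefined with a single class present")
    ranks = rankdata(s, method="average")
    s_p = float(ranks[y == 1].sum())
    return (s_p - n_p * (n_p + 1) / 2) / (n_p * n_n)


def evaluate_predictions(labels, predictions, scores=None) -> MetricReport:
    """Full MetricReport from hard predictions and (optionally) scores.

    AUC uses continuous positive-class scores when given; with hard labels
    only, the predictions themselves are ranked (a degenerate but defined
    two-level AUC).  If only one class is present AUC is reported as None.
    """
    report = compute_metrics(confusion_counts(labels, predictions))
    try:
        report.auc = auc_rank(labels,
                              predictions if scores is None else scores)
    except UndefinedMetricError:
        report.auc = None
    return report
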
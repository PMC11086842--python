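"""Chi-square scoring of binary features against binary labels, and top-k selection.

Each binary feature is scored by the 2x2 contingency statistic
chi2 = sum_ij (O_ij - E_ij)^2 / E_ij with E_ij = (row_i * col_j) / I,
no continuity correction, no p-values: the raw statistic is used purely as a
ranking criterion (higher = stronger dependence on the label).  Degenerate
tables (constant feature or constant labels) score 0.  Ranking is descending
by score with ties broken by ascending column index, which makes selection
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import BinarizedMatrix

__all__ = ["ChiSquareSelector", "ScoredFeatures", "chi2_score", "score_all",
           "select_top_k", "SELECTION_PRESETS"]

#: Feature-count presets used in the reference protocol (0.01%..10% of
#: 205,300 binarized features); any positive integer is accepted.
SELECTION_PRESETS = (20, 200, 2000, 20000)


def _chi2_columns(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized 2x2 chi-square per column of binary matrix F against y."""
    F = F.astype(np.int64)
    y = y.astype(np.int64)
    I = len(y)
    n1 = F.sum(axis=0)            # feature == 1 row total
    c1 = int(y.sum())             # label == 1 column total
    n11 = F.T @ y                 # feature 1, label 1
    n10 = n1 - n11
    n01 = c1 - n11
    n00 = I - n1 - c1 + n11
    # closed form for the 2x2 statistic: I * (ad - bc)^2 / (r0 r1 c0 c1)
    det = n00 * n11 - n01 * n10
    denom = (I - n1) * n1 * (I - c1) * c1
    out = np.zeros(F.shape[1], dtype=float)
    ok = denom > 0
    out[ok] = I * det[ok].astype(float) ** 2 / denom[ok]
    return out


def chi2_score(feature: np.ndarray, labels: np.ndarray) -> float:
    """Chi-square statistic of one 0/1 feature against 0/1 labels.

    Returns 0 for degenerate tables (a zero marginal makes some E_ij = 0).
    """
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if feature.shape != labels.shape or feature.ndim != 1:
        raise ValueError("feature and labels must be 1-D vectors of equal length")
    for name, v in (("feature", feature), ("labels", labels)):
        if not set(np.unique(v).tolist()) <= {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")
    return float(_chi2_columns(feature[:, None], labels)[0])


def _rank_descending(scores: np.ndarray) -> np.ndarray:
    """Permutation ordering columns by descending score, ties by ascending index."""
    return np.lexsort((np.arange(len(scores)), -scores))


@dataclass
class ScoredFeatures:
    """Per-column chi-square scores with a deterministic total rank order."""

    column_ids: list[str]
    chi2: np.ndarray
    rank: np.ndarray  # rank[r] = column index of the r-th best feature

    def top_k(self, k: int) -> list[int]:
        if not 1 <= k <= len(self.column_ids):
            raise ValueError(
                f"k must be in [1, {len(self.column_ids)}], got {k}")
        return self.rank[:k].tolist()


def score_all(data: BinarizedMatrix) -> ScoredFeatures:
    """Score every binary column of a labeled binarized matrix."""
    if data.labels is None:
        raise ValueError("binarized matrix has no labels; cannot score features")
    scores = _chi2_columns(np.asarray(data.values), data.labels)
    return ScoredFeatures(list(data.column_ids), scores, _rank_descending(scores))


def select_top_k(scored: ScoredFeatures, k: int) -> list[int]:
    """Column indices of the k highest-scoring features, in rank order."""
    return scored.top_k(k)


class ChiSquareSelector(SelectorMixin, BaseEstimator):
    """Select the ``k`` binary features most dependent on the binary label.

    scikit-learn selector: ``fit(X, y)`` computes one 2x2 chi-square
    statistic per column, ``transform`` keeps the top ``k`` (ties broken by
    ascending column index).  ``ranking_`` preserves the selection order for
    downstream reporting.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
    ranking_ : ndarray, all columns ordered best-first.
    selected_ : ndarray of the k retained column indices, rank order.
    """

    def __init__(self, k: int = 20):
        self.k = k

    def fit(self, X, y):
        X = check_array(X, dtype=None)
        y = np.asarray(y)
        if not set(np.unique(X).tolist()) <= {0, 1}:
            raise ValueError("ChiSquareSelector expects a 0/1 feature matrix")
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k must be in [1, {X.shape[1]}], got {self.k}")
        self.n_features_in_ = X.shape[1]
        self.scores_ = _chi2_columns(X.astype(np.int64), y.astype(int))
        self.ranking_ = _rank_descending(self.scores_)
        self.selected_ = self.ranking_[: self.k]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "selected_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask
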
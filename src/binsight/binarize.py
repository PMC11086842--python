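"""Min-max normalization and one-hot interval binarization ("binarilization").

Each continuous gene is rescaled to [0, 1] and expanded into K mutually
exclusive 0/1 indicator features, one per equal-width interval
[k/K, (k+1)/K) — the top interval is closed at 1.0 so that the maximum of a
min-max-normalized column still lands in exactly one bin.  The transform is
exposed both as a scikit-learn transformer (:class:`OneHotBinarizer`) and as
thin functions over :class:`~binsight.containers.ExpressionMatrix`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import BinarizedMatrix, BinMap, ExpressionMatrix

__all__ = ["OneHotBinarizer", "minmax_normalize", "binarize", "bin_interval"]

DEFAULT_BINS = 10


def _bin_edges(K: int) -> np.ndarray:
    return np.array([k / K for k in range(K + 1)])


def _assign_bins(V: np.ndarray, K: int) -> np.ndarray:
    """Bin index per entry: largest k with V >= k/K, capped at K-1.

    Replicates the membership test v in [k/K, (k+1)/K) for v < 1 and assigns
    v = 1.0 to the top (closed) bin.
    """
    idx = np.searchsorted(_bin_edges(K), V, side="right") - 1
    return np.minimum(idx, K - 1)


def _one_hot(V: np.ndarray, K: int) -> np.ndarray:
    n, p = V.shape
    bins = _assign_bins(V, K)
    out = np.zeros((n, p * K), dtype=np.int8)
    cols = np.arange(p) * K + bins  # gene-major, bin-ascending
    out[np.repeat(np.arange(n), p), cols.ravel()] = 1
    return out


class OneHotBinarizer(TransformerMixin, BaseEstimator):
    """Expand each continuous feature into ``n_bins`` one-hot interval features.

    ``fit`` learns per-feature min/max; ``transform`` min-max rescales to
    [0, 1] (constant features map to all zeros, hence bin 0) and emits the
    indicator block per feature.  Output columns are ordered feature-major,
    bin-ascending and named ``"<feature>|bin<k>"``.

    Parameters
    ----------
    n_bins : int, default 10
        Number of equal-width intervals per feature (K).
    normalize : bool, default True
        Apply the fitted min-max rescaling in ``transform``.  With False the
        input must already lie in [0, 1].
    clip : bool, default False
        Clip rescaled values into [0, 1] instead of raising.  Only relevant
        when transforming data outside the fitted range (e.g. a held-out set
        under train-only normalization statistics).

    Attributes
    ----------
    data_min_, data_max_ : ndarray of shape (n_features,)
    bin_map_ : BinMap mapping output columns back to (feature, interval).
    feature_names_in_ : ndarray of input names when fit on a DataFrame.
    """

    def __init__(self, n_bins: int = DEFAULT_BINS, normalize: bool = True,
                 clip: bool = False):
        self.n_bins = n_bins
        self.normalize = normalize
        self.clip = clip

    def fit(self, X, y=None):
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        names = list(X.columns.astype(str)) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, dtype=float, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        else:
            names = [f"x{j}" for j in range(self.n_features_in_)]
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.bin_map_ = BinMap(names, self.n_bins)
        return self

    def _rescale(self, X: np.ndarray) -> np.ndarray:
        rng = self.data_max_ - self.data_min_
        safe = np.where(rng > 0, rng, 1.0)
        V = (X - self.data_min_) / safe
        V[:, rng == 0] = 0.0
        return np.clip(V, 0.0, 1.0) if self.clip else V

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "bin_map_")
        ids = list(X.index) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        V = self._rescale(X) if self.normalize else np.asarray(X, dtype=float)
        _check_unit_range(V, ids, self.bin_map_.gene_ids)
        return _one_hot(V, self.n_bins)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "bin_map_")
        return np.asarray(self.bin_map_.column_ids, dtype=object)


def _check_unit_range(V, sample_ids, gene_ids) -> None:
    bad = np.argwhere((V < 0) | (V > 1))
    if bad.size:
        i, j = bad[0]
        sid = sample_ids[i] if sample_ids is not None else f"row {i}"
        raise ValueError(
            f"value {V[i, j]:g} outside [0, 1] at sample {sid}, "
            f"gene {gene_ids[j]}; run minmax_normalize first")


def minmax_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every gene column to [0, 1] via (x - min)/(max - min).

    Constant columns (max == min) map to all zeros.  IDs and labels are
    carried through unchanged.
    """
    X = matrix.values
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    V = (X - lo) / safe
    V[:, rng == 0] = 0.0
    return ExpressionMatrix(V, list(matrix.sample_ids), list(matrix.gene_ids),
                            None if matrix.labels is None else matrix.labels.copy())


def binarize(matrix: ExpressionMatrix, K: int = DEFAULT_BINS) -> BinarizedMatrix:
    """One-hot binarize an already-normalized matrix into J*K binary columns.

    Column ``j*K + k`` of sample ``i`` is 1 iff its normalized value lies in
    [k/K, (k+1)/K); the top bin additionally captures the value 1.0, so each
    (sample, gene) pair activates exactly one column.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    V = matrix.values
    _check_unit_range(V, matrix.sample_ids, matrix.gene_ids)
    bm = BinMap(list(matrix.gene_ids), K)
    return BinarizedMatrix(_one_hot(V, K), bm, list(matrix.sample_ids),
                           None if matrix.labels is None else matrix.labels.copy())


def bin_interval(bin_map: BinMap, column: int) -> tuple[str, float, float, bool]:
    """Return (gene_id, lower, upper, closed_upper) for a binary column."""
    e = bin_map[column]
    return e.gene_id, e.lower, e.upper, e.closed_upper
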
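"""End-to-end experiment driver.

normalize -> one-hot binarize (K bins/gene) -> chi-square ranking -> for each
feature-count preset and repeat: stratified 80:20 split, random
hyperparameter search with stratified CV on the training part, refit, and
test-set evaluation; per-repeat rows are aggregated into per-(family,
feature-count) means.

By default normalization statistics and feature ranking are computed on the
full matrix before splitting, reproducing the protocol this package models;
``selection_scope="train"`` recomputes both inside each repeat's training
partition only (the leakage-safe variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .binarize import DEFAULT_BINS, OneHotBinarizer
from .containers import ExpressionMatrix
from .metrics import evaluate_predictions
from .models import BackendError, FAMILIES
from .search import DEFAULT_DRAWS, DEFAULT_FOLDS, SearchResult, random_search
from .select import _chi2_columns, _rank_descending

__all__ = ["ExperimentConfig", "ExperimentReport", "stratified_split",
           "run_experiment", "DEFAULT_TRAIN_FRACTION", "DEFAULT_REPEATS"]

logger = logging.getLogger(__name__)

DEFAULT_TRAIN_FRACTION = 0.8
DEFAULT_REPEATS = 10

_METRIC_COLS = ["accuracy", "sensitivity", "specificity", "gmean", "mcc",
                "precision", "recall", "f1", "auc"]


def stratified_split(labels, train_fraction: float = DEFAULT_TRAIN_FRACTION,
                     seed: int | None = None):
    """Deterministic stratified partition into (train_idx, test_idx).

    Per class the train count is the nearest integer to
    train_fraction * class size (clamped so both sides keep at least one
    sample of each class).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(
                f"class {cls} has {len(idx)} sample(s); need >= 2 to split")
        rng.shuffle(idx)
        n_train = int(np.floor(len(idx) * train_fraction + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


@dataclass
class ExperimentConfig:
    """All knobs of one experiment run."""

    K: int = DEFAULT_BINS
    feature_counts: tuple = (20,)
    families: tuple = ("random_forest",)
    n_draws: int = DEFAULT_DRAWS
    folds: int = DEFAULT_FOLDS
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    repeats: int = DEFAULT_REPEATS
    seed: int = 0
    selection_scope: str = "all"   # "all" (protocol default) | "train"
    search_once: bool = False      # reuse repeat 0's winning config

    def __post_init__(self) -> None:
        self.feature_counts = tuple(int(k) for k in self.feature_counts)
        self.families = tuple(self.families)
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}; "
                             f"choose from {FAMILIES}")
        if self.selection_scope not in ("all", "train"):
            raise ValueError("selection_scope must be 'all' or 'train'")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentReport:
    """Per-repeat metric rows, their per-cell means, and the search log."""

    rows: pd.DataFrame
    means: pd.DataFrame
    searches: dict = field(default_factory=dict)  # (family, k, repeat) -> SearchResult
    config: ExperimentConfig | None = None
    errors: list = field(default_factory=list)

    def best_repeat(self, family: str, n_features: int) -> int:
        """Repeat index with the highest test F1 for one (family, size) cell."""
        cell = self.rows[(self.rows.family == family)
                         & (self.rows.n_features == n_features)]
        if cell.empty:
            raise KeyError(f"no rows for ({family}, {n_features})")
        return int(cell.loc[cell.f1.idxmax(), "repeat"])


def _binarize_full(matrix: ExpressionMatrix, K: int):
    binner = OneHotBinarizer(n_bins=K)
    B = binner.fit_transform(matrix.to_frame())
    return binner, B


def _repeat_seed(master: int, r: int) -> int:
    return (int(master) + r) % (2 ** 31 - 1)


def run_experiment(matrix: ExpressionMatrix,
                   config: ExperimentConfig) -> ExperimentReport:
    """Run the full protocol and aggregate per-repeat test metrics."""
    if matrix.labels is None:
        raise ValueError("run_experiment needs a labeled matrix")
    y = matrix.labels
    frame = matrix.to_frame()

    shared = None
    if config.selection_scope == "all":
        binner, B = _binarize_full(matrix, config.K)
        scores = _chi2_columns(B, y)
        ranking = _rank_descending(scores)
        shared = (binner, B, ranking)

    rows, searches, errors = [], {}, []
    for r in range(config.repeats):
        seed_r = _repeat_seed(config.seed, r)
        train_idx, test_idx = stratified_split(y, config.train_fraction, seed_r)
        if config.selection_scope == "train":
            binner = OneHotBinarizer(n_bins=config.K, clip=True)
            B_train = binner.fit_transform(frame.iloc[train_idx])
            B_test = binner.transform(frame.iloc[test_idx])
            ranking = _rank_descending(_chi2_columns(B_train, y[train_idx]))
        else:
            binner, B, ranking = shared
            B_train, B_test = B[train_idx], B[test_idx]

        for k in config.feature_counts:
            if k > B_train.shape[1]:
                raise ValueError(
                    f"feature count {k} exceeds {B_train.shape[1]} binary columns")
            cols = ranking[:k]
            Xtr, Xte = B_train[:, cols].astype(float), B_test[:, cols].astype(float)
            for family in config.families:
                try:
                    reuse = (config.search_once and r > 0
                             and (family, k, 0) in searches)
                    if reuse:
                        result = searches[(family, k, 0)]
                    else:
                        result = random_search(family, Xtr, y[train_idx],
                                               n_draws=config.n_draws,
                                               folds=config.folds, seed=seed_r)
                    searches[(family, k, r)] = result
                    from .models import fit_predict
                    pred, score = fit_predict(family, result.best_config,
                                              Xtr, y[train_idx], Xte,
                                              seed=seed_r)
                    report = evaluate_predictions(y[test_idx], pred, score)
                    row = {"family": family, "n_features": k, "repeat": r,
                           "seed": seed_r, **{m: getattr(report, m)
                                              for m in _METRIC_COLS}}
                    rows.append(row)
                except (BackendError, ValueError) as exc:
                    logger.error("cell (%s, k=%d, repeat=%d) failed: %s",
                                 family, k, r, exc)
                    errors.append({"family": family, "n_features": k,
                                   "repeat": r, "error": str(exc)})

    rows_df = pd.DataFrame(rows)
    if rows_df.empty:
        raise RuntimeError(f"every experiment cell failed: {errors}")
    means = (rows_df.groupby(["family", "n_features"], as_index=False)
             [_METRIC_COLS].mean())
    return ExperimentReport(rows=rows_df, means=means, searches=searches,
                            config=config, errors=errors)
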
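"""Random hyperparameter search with stratified k-fold cross-validation.

Candidates are drawn uniformly from a family's declared space (default 200
draws) and scored by mean cross-validated F-Measure; the best-scoring
candidate wins, ties going to the first one encountered so a fixed seed
fully determines the outcome.  Finite spaces smaller than the draw budget
(the SVM's four kernels) are enumerated once each instead of redundantly
resampled.  If the minority class is smaller than the requested fold count
the folds are reduced to the minority count with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_is_fitted

from .metrics import confusion_counts, compute_metrics
from .models import build_estimator, default_space, sample_config

__all__ = ["SearchResult", "RandomParameterSearchCV", "random_search",
           "DEFAULT_DRAWS", "DEFAULT_FOLDS"]

logger = logging.getLogger(__name__)

DEFAULT_DRAWS = 200
DEFAULT_FOLDS = 10


@dataclass
class SearchResult:
    """Outcome of one random search: the winner plus the full candidate log."""

    family: str
    best_config: dict
    best_score: float
    log: list[dict] = field(default_factory=list)  # config, fold_f1, mean_f1
    seed: int | None = None
    n_folds: int = DEFAULT_FOLDS

    def to_dict(self) -> dict:
        return {"family": self.family, "best_config": self.best_config,
                "best_score": self.best_score, "seed": self.seed,
                "n_folds": self.n_folds, "log": self.log}


class RandomParameterSearchCV(BaseEstimator):
    """Random-search + CV model selector for one classifier family.

    ``fit(X, y)`` draws ``n_draws`` configurations, scores each by mean
    F-Measure over stratified ``cv``-fold cross-validation, refits the
    winner on all of (X, y) and exposes it as ``best_estimator_``.

    Attributes
    ----------
    best_params_, best_score_, cv_results_ (the per-candidate log),
    best_estimator_, search_result_.
    """

    def __init__(self, family: str = "random_forest",
                 n_draws: int = DEFAULT_DRAWS, cv: int = DEFAULT_FOLDS,
                 random_state: int | None = None):
        self.family = family
        self.n_draws = n_draws
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("random search needs both classes present in y")
        minority = int(counts.min())
        n_folds = self.cv
        if minority < n_folds:
            warnings.warn(
                f"minority class has {minority} samples < {n_folds} folds; "
                f"reducing to {minority}-fold CV", UserWarning)
            n_folds = minority
        space = default_space(self.family, input_size=X.shape[1])
        rng = np.random.default_rng(self.random_state)
        if space.size is not None and space.size <= self.n_draws:
            candidates = space.enumerate()
            logger.info("%s space is finite (%d configs <= %d draws); "
                        "evaluating each once", self.family, len(candidates),
                        self.n_draws)
        else:
            candidates = [sample_config(space, rng) for _ in range(self.n_draws)]
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=_fold_seed(self.random_state))
        folds = list(splitter.split(X, y))
        log, best_idx, best_mean = [], -1, -np.inf
        for idx, config in enumerate(candidates):
            fold_f1 = [self._fold_f1(config, X, y, tr, te)
                       for tr, te in folds]
            mean_f1 = float(np.mean(fold_f1))
            log.append({"config": config, "fold_f1": fold_f1,
                        "mean_f1": mean_f1})
            if mean_f1 > best_mean:  # strict: first-encountered wins ties
                best_idx, best_mean = idx, mean_f1
        self.best_params_ = candidates[best_idx]
        self.best_score_ = best_mean
        self.cv_results_ = log
        self.search_result_ = SearchResult(
            family=self.family, best_config=self.best_params_,
            best_score=self.best_score_, log=log, seed=self.random_state,
            n_folds=n_folds)
        self.best_estimator_ = build_estimator(
            self.family, self.best_params_, seed=_fold_seed(self.random_state))
        self.best_estimator_.fit(X, y)
        return self

    def _fold_f1(self, config, X, y, train_idx, test_idx) -> float:
        model = build_estimator(self.family, config,
                                seed=_fold_seed(self.random_state))
        model.fit(X[train_idx], y[train_idx])
        pred = np.asarray(model.predict(X[test_idx])).astype(int)
        return compute_metrics(confusion_counts(y[test_idx], pred)).f1

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict_proba(X)


def _fold_seed(random_state: int | None) -> int | None:
    return None if random_state is None else int(random_state) % (2 ** 31 - 1)


def random_search(family: str, X, y, n_draws: int = DEFAULT_DRAWS,
                  folds: int = DEFAULT_FOLDS,
                  seed: int | None = None) -> SearchResult:
    """Functional wrapper: run the search and return its SearchResult."""
    searcher = RandomParameterSearchCV(family=family, n_draws=n_draws,
                                       cv=folds, random_state=seed)
    searcher.fit(np.asarray(X, dtype=float), np.asarray(y))
    return searcher.search_result_
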
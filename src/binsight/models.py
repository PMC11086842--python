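"""The five classifier families behind a uniform interface.

Each family (neural network, decision tree, random forest, XGBoost, SVM)
carries a declared hyperparameter search space; configurations are drawn by
independent uniform sampling per dimension — discrete uniform on choice sets
and integer ranges, continuous uniform on real ranges.  Decision tree,
random forest and SVM are scikit-learn backends, XGBoost is the xgboost
package, and the neural network is the package's own numpy MLP (Adadelta,
dropout, ReLU/ELU/GELU/Swish).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .nn import MLPBinaryClassifier

__all__ = ["FAMILIES", "SearchSpace", "default_space", "sample_config",
           "build_estimator", "fit_predict", "BackendError"]

FAMILIES = ("neural_network", "decision_tree", "random_forest",
            "xgboost", "svm")


class BackendError(RuntimeError):
    """A classifier backend failed; carries family and configuration."""

    def __init__(self, family: str, config: dict, cause: Exception):
        super().__init__(f"{family} backend failed with config {config}: {cause}")
        self.family, self.config, self.cause = family, config, cause


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def sample(self, rng):
        return self.choices[rng.integers(len(self.choices))]

    def contains(self, v):
        return v in self.choices

    def grid(self):
        return list(self.choices)


@dataclass(frozen=True)
class IntRange:
    low: int
    high: int  # inclusive

    def sample(self, rng):
        return int(rng.integers(self.low, self.high + 1))

    def contains(self, v):
        return isinstance(v, (int, np.integer)) and self.low <= v <= self.high

    def grid(self):
        return list(range(self.low, self.high + 1))


@dataclass(frozen=True)
class FloatRange:
    low: float
    high: float

    def sample(self, rng):
        return float(rng.uniform(self.low, self.high))

    def contains(self, v):
        return self.low <= v <= self.high

    def grid(self):
        raise ValueError("continuous dimension has no finite grid")


@dataclass
class SearchSpace:
    """Named hyperparameter dimensions for one classifier family."""

    family: str
    dimensions: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> dict:
        return {name: dim.sample(rng) for name, dim in self.dimensions.items()}

    def contains(self, config: dict) -> bool:
        return (set(config) == set(self.dimensions)
                and all(self.dimensions[k].contains(v)
                        for k, v in config.items()))

    @property
    def size(self) -> int | None:
        """Number of distinct configurations, or None if uncountable."""
        total = 1
        for dim in self.dimensions.values():
            if isinstance(dim, FloatRange) and dim.low < dim.high:
                return None
            total *= len(dim.grid()) if not isinstance(dim, FloatRange) else 1
        return total

    def enumerate(self) -> list[dict]:
        names = list(self.dimensions)
        grids = [self.dimensions[n].grid() for n in names]
        return [dict(zip(names, combo)) for combo in itertools.product(*grids)]


_TREE_DIMS = {
    "criterion": Categorical(("gini", "entropy")),
    "max_depth": IntRange(10, 100),
    "min_samples_split": IntRange(2, 10),
    "min_samples_leaf": IntRange(1, 4),
    "max_features": Categorical(("sqrt", "log2")),
}


def default_space(family: str, input_size: int | None = None) -> SearchSpace:
    """The declared search range for one family.

    ``input_size`` (post-selection feature count) bounds the neural
    network's nodes-per-layer dimension and is required for that family.
    """
    if family == "decision_tree":
        return SearchSpace(family, dict(_TREE_DIMS))
    if family == "random_forest":
        return SearchSpace(family, {"n_trees": IntRange(100, 1000), **_TREE_DIMS})
    if family == "xgboost":
        return SearchSpace(family, {
            "n_trees": IntRange(100, 1000),
            "max_depth": IntRange(10, 100),
            "learning_rate": FloatRange(0.01, 0.1),
            "gamma": FloatRange(0.01, 0.1),
            "min_child_weight": FloatRange(0.01, 0.1),
            "reg_lambda": FloatRange(0.01, 0.1),
        })
    if family == "svm":
        return SearchSpace(family, {
            "kernel": Categorical(("linear", "poly", "rbf", "sigmoid")),
        })
    if family == "neural_network":
        if input_size is None:
            raise ValueError(
                "neural_network space needs input_size (nodes-per-layer "
                "upper bound is the input dimensionality)")
        if input_size < 2:
            raise ValueError("neural_network needs input_size >= 2")
        return SearchSpace(family, {
            "n_layers": Categorical((1, 2, 3)),
            "nodes_per_layer": IntRange(2, int(input_size)),
            "dropout_rate": FloatRange(0.1, 0.3),
            "activation": Categorical(("relu", "elu", "gelu", "swish")),
            "learning_rate": Categorical((1.0,)),
            "optimizer": Categorical(("adadelta",)),
        })
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def sample_config(space: SearchSpace, rng: np.random.Generator) -> dict:
    """One configuration: independent uniform draw per dimension."""
    return space.sample(rng)


def build_estimator(family: str, config: dict, seed: int | None = None):
    """Instantiate a seeded backend classifier for a configuration."""
    if family == "decision_tree":
        return DecisionTreeClassifier(
            criterion=config["criterion"], max_depth=config["max_depth"],
            min_samples_split=config["min_samples_split"],
            min_samples_leaf=config["min_samples_leaf"],
            max_features=config["max_features"], random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=config["n_trees"], criterion=config["criterion"],
            max_depth=config["max_depth"],
            min_samples_split=config["min_samples_split"],
            min_samples_leaf=config["min_samples_leaf"],
            max_features=config["max_features"], random_state=seed, n_jobs=1)
    if family == "xgboost":
        return XGBClassifier(
            n_estimators=config["n_trees"], max_depth=config["max_depth"],
            learning_rate=config["learning_rate"], gamma=config["gamma"],
            min_child_weight=config["min_child_weight"],
            reg_lambda=config["reg_lambda"], random_state=seed or 0,
            n_jobs=1, tree_method="hist", eval_metric="logloss",
            verbosity=0)
    if family == "svm":
        return SVC(kernel=config["kernel"], random_state=seed)
    if family == "neural_network":
        return MLPBinaryClassifier(
            hidden_layer_sizes=(config["nodes_per_layer"],) * config["n_layers"],
            dropout=config["dropout_rate"], activation=config["activation"],
            learning_rate=config["learning_rate"], random_state=seed)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def _positive_scores(model, X) -> np.ndarray:
    """Continuous positive-class score: probability when available,
    decision value otherwise, hard prediction as a last resort."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        cols = list(getattr(model, "classes_", [0, 1]))
        return proba[:, cols.index(1)] if 1 in cols else 1.0 - proba[:, 0]
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return model.predict(X).astype(float)


def fit_predict(family: str, config: dict, X_train, y_train, X_test,
                seed: int | None = None):
    """Train a backend and return (hard 0/1 predictions, positive scores)."""
    try:
        model = build_estimator(family, config, seed=seed)
        model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
        X_test = np.asarray(X_test, dtype=float)
        pred = np.asarray(model.predict(X_test)).astype(int)
        scores = _positive_scores(model, X_test)
        return pred, scores
    except (ValueError, RuntimeError) as exc:  # surface context with the failure
        raise BackendError(family, config, exc) from exc
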
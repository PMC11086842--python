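"""Shapley-value attribution of predictions to binary range-features.

Two independent engines are provided:

* :func:`exact_shapley` — literal subset enumeration of the Shapley value
  with an interventional value function: v(S) replaces the features in S
  with the explained sample's values across a background set and averages
  the model output.  Exponential in the feature count, hence capped
  (default 15 features) — but exact, model-agnostic, and the reference
  the rest of the module is validated against.

* :func:`tree_shapley` — an exact interventional engine for scikit-learn
  decision trees and random forests.  For each (sample, background) pair it
  walks every root-to-leaf path, classifies the path's feature constraints
  as satisfied by the sample only, the background row only, or both, and
  accumulates each leaf's value with closed-form coalition-counting weights.
  Linear in leaves instead of exponential in features.

Attributions over selected binarized features are mapped back through the
bin map into human-readable "(gene) in [lo, hi)" interval reports ranked by
mean absolute attribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .containers import BinMap
from .models import _positive_scores

__all__ = ["AttributionMatrix", "IntervalReport", "exact_shapley",
           "tree_shapley", "attribute", "interval_report",
           "DEFAULT_MAX_EXACT_FEATURES", "DEFAULT_BACKGROUND_SIZE"]

DEFAULT_MAX_EXACT_FEATURES = 15
DEFAULT_BACKGROUND_SIZE = 100


# ---------------------------------------------------------------------------
# exact subset enumeration
# ---------------------------------------------------------------------------

def exact_shapley(predict_fn, x, background, max_features: int =
                  DEFAULT_MAX_EXACT_FEATURES):
    """Exact Shapley attributions for one sample by subset enumeration.

    phi_i = sum over S subset of F\\{i} of |S|!(|F|-|S|-1)!/|F|! times
    (v(S+i) - v(S)), with v(S) the mean of ``predict_fn`` over background
    rows whose features in S are replaced by ``x``.

    Returns (phi, base_value) with base_value = v(empty set).
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    F = len(x)
    if background.shape[1] != F:
        raise ValueError("background feature count does not match x")
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if F > max_features:
        raise ValueError(
            f"{F} features exceeds the exact-enumeration cap of "
            f"{max_features}; use the tree engine for larger models")
    n_masks = 1 << F
    B = background.shape[0]
    v = np.empty(n_masks)
    bit_on = np.array([[(m >> i) & 1 for i in range(F)]
                       for m in range(n_masks)], dtype=bool)
    chunk = max(1, 65536 // max(B, 1))
    for start in range(0, n_masks, chunk):
        masks = range(start, min(start + chunk, n_masks))
        rows = np.repeat(background, len(masks), axis=0).reshape(B, len(masks), F)
        rows = np.swapaxes(rows, 0, 1).copy()  # (n_masks_chunk, B, F)
        for mi, m in enumerate(masks):
            rows[mi][:, bit_on[m]] = x[bit_on[m]]
        preds = np.asarray(predict_fn(rows.reshape(-1, F)), dtype=float)
        v[start:start + len(masks)] = preds.reshape(len(masks), B).mean(axis=1)
    sizes = bit_on.sum(axis=1)
    w = np.array([factorial(s) * factorial(F - s - 1) / factorial(F)
                  for s in range(F)])
    phi = np.zeros(F)
    all_masks = np.arange(n_masks)
    for i in range(F):
        without = all_masks[~bit_on[:, i]]
        phi[i] = np.sum(w[sizes[without]] * (v[without | (1 << i)] - v[without]))
    return phi, float(v[0])


# ---------------------------------------------------------------------------
# exact interventional engine for tree ensembles
# ---------------------------------------------------------------------------

def _leaf_bounds(tree, class_one_index, d):
    """Per-leaf interval bounds: each root-to-leaf path is the conjunction
    ``lower[f] < value[f] <= upper[f]`` per feature (scikit-learn splits
    send ``value <= threshold`` left).  Returns (L, U, vals) with L, U of
    shape (n_leaves, d)."""
    t = tree.tree_
    L, U, vals = [], [], []

    def walk(node, lower, upper):
        if t.children_left[node] == -1:  # leaf
            val = np.asarray(t.value[node], dtype=float).ravel()
            if class_one_index is not None:
                total = val.sum()
                vals.append(val[class_one_index] / total if total > 0 else 0.0)
            else:
                vals.append(float(val[0]))
            L.append(lower.copy())
            U.append(upper.copy())
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        saved = upper[f]
        upper[f] = min(upper[f], thr)
        walk(t.children_left[node], lower, upper)
        upper[f] = saved
        saved = lower[f]
        lower[f] = max(lower[f], thr)
        walk(t.children_right[node], lower, upper)
        lower[f] = saved

    walk(0, np.full(d, -np.inf), np.full(d, np.inf))
    return np.array(L), np.array(U), np.array(vals)


def _coalition_weight_tables(d: int):
    """Closed-form leaf weights for the path-counting formulation.

    For a leaf whose path requires the ``a`` features of set A to come from
    the explained sample and the ``b`` features of set B to stay at
    background values, the leaf contributes +W_in(a, b) to each feature of
    A and -W_out(a, b) to each feature of B, summing the Shapley coalition
    weights over the d-a-b free features:

        W_in(a,b)  = sum_j C(f,j) (a-1+j)! (d-a-j)!   / d!
        W_out(a,b) = sum_j C(f,j) (a+j)!   (d-a-j-1)! / d!   with f = d-a-b.

    Returned as dense (d+1, d+1) lookup tables indexed by [a, b]
    (zero where undefined or infeasible).
    """
    fact = [factorial(k) for k in range(d + 1)]
    dfact = fact[d]
    w_in = np.zeros((d + 1, d + 1))
    w_out = np.zeros((d + 1, d + 1))
    for a in range(d + 1):
        for b in range(d + 1 - a):
            f = d - a - b
            if a >= 1:
                w_in[a, b] = sum(comb(f, j) * fact[a - 1 + j] * fact[d - a - j]
                                 for j in range(f + 1)) / dfact
            if b >= 1 and d - a - 1 >= 0:
                w_out[a, b] = sum(comb(f, j) * fact[a + j] * fact[d - a - j - 1]
                                  for j in range(f + 1)) / dfact
    return w_in, w_out


def _component_trees(model):
    if isinstance(model, (DecisionTreeClassifier, DecisionTreeRegressor)):
        return [model], isinstance(model, DecisionTreeClassifier)
    if isinstance(model, RandomForestClassifier):
        return list(model.estimators_), True
    raise TypeError(
        f"tree engine supports decision trees and random forests, "
        f"not {type(model).__name__}")


def tree_shapley(model, X, background):
    """Exact interventional Shapley values for a tree model.

    Averages the per-path attribution over every (sample, background row,
    tree) triple; for classifiers the explained output is the predicted
    probability of class 1.  Returns (phi_matrix, base_value).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    d = X.shape[1]
    trees, is_classifier = _component_trees(model)
    if is_classifier:
        cls = list(np.asarray(trees[0].classes_).tolist())
        class_one = cls.index(1)
    else:
        class_one = None
    win_tab, wout_tab = _coalition_weight_tables(d)
    phi = np.zeros((X.shape[0], d))
    base = 0.0
    for tree in trees:
        L, U, vals = _leaf_bounds(tree, class_one, d)
        rel = np.isfinite(L) | np.isfinite(U)          # (leaves, d)
        z_ok = (Z[:, None, :] > L) & (Z[:, None, :] <= U)  # (B, leaves, d)
        # background row's own leaf: all relevant constraints satisfied
        z_leaf = ~np.any(rel & ~z_ok, axis=2)          # (B, leaves)
        base += float((z_leaf * vals).sum())
        for i, x in enumerate(X):
            x_ok = (x > L) & (x <= U)                  # (leaves, d)
            need_x = rel & x_ok[None] & ~z_ok          # set A per (z, leaf)
            need_z = rel & z_ok & ~x_ok[None]          # set B per (z, leaf)
            alive = ~np.any(rel & ~x_ok[None] & ~z_ok, axis=2)
            a = need_x.sum(axis=2)
            b = need_z.sum(axis=2)
            gain = np.where(alive, vals[None, :] * win_tab[a, b], 0.0)
            loss = np.where(alive, vals[None, :] * wout_tab[a, b], 0.0)
            phi[i] += np.einsum("bl,bld->d", gain, need_x)
            phi[i] -= np.einsum("bl,bld->d", loss, need_z)
    scale = len(trees) * Z.shape[0]
    return phi / scale, base / scale


# ---------------------------------------------------------------------------
# attribution driver + interval reports
# ---------------------------------------------------------------------------

@dataclass
class AttributionMatrix:
    """Per-sample, per-feature attributions with their provenance."""

    values: np.ndarray            # (n_samples, n_features)
    base_value: float             # expected model output over the background
    feature_values: np.ndarray    # the explained (binary) inputs, same shape
    column_ids: list[str]
    bin_map: BinMap | None = None
    columns: list[int] | None = None  # original binary-column indices

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def attribute(model, X_test, background, engine: str = "auto",
              bin_map: BinMap | None = None,
              columns: list[int] | None = None,
              max_features: int = DEFAULT_MAX_EXACT_FEATURES,
              column_ids: list[str] | None = None) -> AttributionMatrix:
    """Attribute model outputs on X_test to its input features.

    engine : {"auto", "exact", "tree"}
        "tree" runs the closed-form interventional engine (tree models
        only); "exact" enumerates subsets (feature count capped); "auto"
        prefers the tree engine and falls back to exact when feasible.
    """
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    F = X_test.shape[1]
    if engine not in ("auto", "exact", "tree"):
        raise ValueError(f"unknown engine {engine!r}")
    use_tree = False
    if engine == "tree":
        use_tree = True
    elif engine == "auto":
        try:
            _component_trees(model)
            use_tree = True
        except TypeError:
            if F > max_features:
                raise ValueError(
                    f"no tree engine for {type(model).__name__} and "
                    f"{F} features exceeds the exact cap {max_features}")
    if use_tree:
        phi, base = tree_shapley(model, X_test, background)
    else:
        predict_fn = lambda A: _positive_scores(model, A)  # noqa: E731
        rows = [exact_shapley(predict_fn, x, background, max_features)
                for x in X_test]
        phi = np.vstack([r[0] for r in rows])
        base = rows[0][1]
    if column_ids is None:
        if bin_map is not None and columns is not None:
            column_ids = [bin_map[c].column_id for c in columns]
        else:
            column_ids = [f"f{j}" for j in range(F)]
    return AttributionMatrix(values=phi, base_value=base,
                             feature_values=X_test, column_ids=column_ids,
                             bin_map=bin_map, columns=columns)


@dataclass
class IntervalReport:
    """Features ranked by mean |attribution|, named as gene + value range."""

    table: pd.DataFrame  # rank, column_id, gene, interval, mean_abs_attribution,
    #                      frac_positive_when_active

    def to_frame(self) -> pd.DataFrame:
        return self.table


def interval_report(attr: AttributionMatrix, top_n: int | None = None
                    ) -> IntervalReport:
    """Rank features by mean absolute attribution, ties by column order.

    ``frac_positive_when_active`` is, among samples whose binary feature is
    1, the fraction with a positive attribution — a sign summary of whether
    occupying that value range pushes predictions toward the positive class.
    """
    n_feat = attr.n_features
    if top_n is None:
        top_n = n_feat
    if top_n > n_feat:
        raise ValueError(f"top_n={top_n} exceeds {n_feat} features")
    mean_abs = np.abs(attr.values).mean(axis=0)
    order = np.lexsort((np.arange(n_feat), -mean_abs))[:top_n]
    rows = []
    for rank, j in enumerate(order, start=1):
        active = attr.feature_values[:, j] == 1
        frac_pos = (float(np.mean(attr.values[active, j] > 0))
                    if active.any() else 0.0)
        if attr.bin_map is not None and attr.columns is not None:
            entry = attr.bin_map[attr.columns[j]]
            gene, interval = entry.gene_id, entry.interval_text()
        else:
            gene, interval = attr.column_ids[j], ""
        rows.append({"rank": rank, "column_id": attr.column_ids[j],
                     "gene": gene, "interval": interval,
                     "mean_abs_attribution": float(mean_abs[j]),
                     "frac_positive_when_active": frac_pos})
    return IntervalReport(pd.DataFrame(rows))


def beeswarm(attr: AttributionMatrix, path, top_n: int = 10):  # pragma: no cover
    """Optional beeswarm-style summary plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = interval_report(attr, min(top_n, attr.n_features)).table
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(report) + 1.5))
    rng = np.random.default_rng(0)
    for y, (_, row) in enumerate(report.iloc[::-1].iterrows()):
        j = attr.column_ids.index(row["column_id"])
        vals = attr.values[:, j]
        jitter = rng.uniform(-0.18, 0.18, len(vals))
        colors = np.where(attr.feature_values[:, j] == 1, "crimson", "steelblue")
        ax.scatter(vals, y + jitter, s=12, c=colors, alpha=0.7, linewidths=0)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(range(len(report)))
    ax.set_yticklabels([f"{r.gene} {r.interval}" for r in
                        report.iloc[::-1].itertuples()])
    ax.set_xlabel("attribution (impact on positive-class output)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
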
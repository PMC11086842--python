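"""Shapley attribution: exact enumeration, the tree engine, and reports."""

import itertools
from math import factorial

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from binsight import (attribute, exact_shapley, interval_report, tree_shapley)
from binsight.containers import BinMap


@pytest.fixture
def binary_background(rng):
    return (rng.random((12, 6)) < 0.5).astype(float)


def permutation_shapley(predict_fn, x, background):
    """Independent oracle: average marginal contribution over all feature
    orderings, with the same interventional value function."""
    F = len(x)
    background = np.asarray(background, dtype=float)

    def v(S):
        rows = background.copy()
        for i in S:
            rows[:, i] = x[i]
        return float(np.mean(predict_fn(rows)))

    phi = np.zeros(F)
    for order in itertools.permutations(range(F)):
        S = []
        for i in order:
            before = v(S)
            S.append(i)
            phi[i] += v(S) - before
    return phi / factorial(F)


class TestExactShapley:
    def test_additive_model_closed_form(self, rng, binary_background):
        w = rng.normal(size=6)
        f = lambda A: A @ w  # noqa: E731
        x = (rng.random(6) < 0.5).astype(float)
        phi, base = exact_shapley(f, x, binary_background)
        expected = w * (x - binary_background.mean(axis=0))
        np.testing.assert_allclose(phi, expected, atol=1e-8)
        assert base == pytest.approx(float(f(binary_background).mean()))

    def test_efficiency_on_arbitrary_model(self, rng, binary_background):
        w = rng.normal(size=6)
        f = lambda A: np.sin(A @ w) + (A[:, 0] * A[:, 3])  # noqa: E731
        x = (rng.random(6) < 0.5).astype(float)
        phi, base = exact_shapley(f, x, binary_background)
        assert base + phi.sum() == pytest.approx(float(f(x[None])[0]),
                                                 abs=1e-6)

    def test_matches_permutation_enumeration_oracle(self, rng):
        X = (rng.random((40, 5)) < 0.5).astype(float)
        y = ((X[:, 0] + X[:, 2] + X[:, 4]) >= 2).astype(int)
        model = DecisionTreeClassifier(max_depth=4, random_state=0).fit(X, y)
        f = lambda A: model.predict_proba(A)[:, 1]  # noqa: E731
        bg = X[:6]
        x = X[7]
        phi, _ = exact_shapley(f, x, bg)
        np.testing.assert_allclose(phi, permutation_shapley(f, x, bg),
                                   atol=1e-10)

    def test_symmetry_of_duplicated_features(self, rng):
        # model treats features 1 and 2 identically; x and background agree
        f = lambda A: A[:, 1] + A[:, 2] + 0.5 * A[:, 0]  # noqa: E731
        x = np.array([1.0, 1.0, 1.0, 0.0])
        bg = np.tile(np.array([0.0, 0.0, 0.0, 1.0]), (5, 1))
        phi, _ = exact_shapley(f, x, bg)
        assert phi[1] == pytest.approx(phi[2], abs=1e-12)

    def test_null_feature_gets_zero(self, rng, binary_background):
        f = lambda A: A[:, 0] * 2.0 - A[:, 2]  # noqa: E731  (ignores 1,3,4,5)
        x = (rng.random(6) < 0.5).astype(float)
        phi, _ = exact_shapley(f, x, binary_background)
        for i in (1, 3, 4, 5):
            assert phi[i] == pytest.approx(0.0, abs=1e-12)

    def test_feature_cap_refuses_large_inputs(self, rng):
        x = np.zeros(16)
        with pytest.raises(ValueError, match="tree engine"):
            exact_shapley(lambda A: A.sum(1), x, np.zeros((3, 16)))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            exact_shapley(lambda A: A.sum(1), np.zeros(3),
                          np.zeros((0, 3)))


class TestTreeEngine:
    @pytest.mark.parametrize("model_factory", [
        lambda X, y: DecisionTreeClassifier(max_depth=3, random_state=1).fit(X, y),
        lambda X, y: RandomForestClassifier(n_estimators=8, max_depth=3,
                                            random_state=1).fit(X, y),
    ])
    def test_agrees_with_exact_enumeration(self, rng, model_factory):
        X = (rng.random((60, 7)) < 0.5).astype(float)
        y = ((X[:, 0] + 2 * X[:, 3]) >= 2).astype(int)
        model = model_factory(X, y)
        bg = X[:10]
        f = lambda A: model.predict_proba(A)[:, 1]  # noqa: E731
        for x in X[10:14]:
            phi_exact, base_exact = exact_shapley(f, x, bg)
            phi_tree, base_tree = tree_shapley(model, x[None], bg)
            np.testing.assert_allclose(phi_tree[0], phi_exact, atol=1e-4)
            assert base_tree == pytest.approx(base_exact, abs=1e-10)

    def test_efficiency_holds_per_sample(self, rng):
        X = (rng.random((50, 6)) < 0.5).astype(float)
        y = (X[:, 1] > 0).astype(int)
        model = RandomForestClassifier(n_estimators=5, max_depth=4,
                                       random_state=0).fit(X, y)
        bg = X[:8]
        phi, base = tree_shapley(model, X[20:25], bg)
        out = model.predict_proba(X[20:25])[:, 1]
        np.testing.assert_allclose(base + phi.sum(axis=1), out, atol=1e-10)

    def test_unsupported_model_raises(self, rng):
        from sklearn.linear_model import LogisticRegression
        X = rng.random((20, 3))
        y = (X[:, 0] > 0.5).astype(int)
        model = LogisticRegression().fit(X, y)
        with pytest.raises(TypeError, match="tree engine"):
            tree_shapley(model, X[:2], X[:5])


class TestAttribute:
    def test_shape_contract_and_engine_switch(self, rng):
        X = (rng.random((30, 5)) < 0.5).astype(float)
        y = (X[:, 0] > 0).astype(int)
        model = DecisionTreeClassifier(random_state=0).fit(X, y)
        attr = attribute(model, X[:4], X[4:14], engine="tree")
        assert attr.values.shape == (4, 5)
        attr2 = attribute(model, X[:4], X[4:14], engine="exact")
        np.testing.assert_allclose(attr.values, attr2.values, atol=1e-4)

    def test_constant_model_attributes_nothing(self, rng):
        X = (rng.random((20, 4)) < 0.5).astype(float)
        model = DecisionTreeClassifier().fit(X, np.ones(20, dtype=int))
        # single-class tree: every leaf predicts 1 with certainty
        attr = attribute(model, X[:3], X[3:9], engine="tree")
        np.testing.assert_allclose(attr.values, 0.0, atol=1e-12)

    def test_non_tree_model_over_cap_errors(self, rng):
        from sklearn.linear_model import LogisticRegression
        X = rng.random((25, 20))
        y = (X[:, 0] > 0.5).astype(int)
        model = LogisticRegression().fit(X, y)
        with pytest.raises(ValueError, match="exceeds the exact cap"):
            attribute(model, X[:2], X[:5], engine="auto", max_features=15)


class TestIntervalReport:
    def _attr(self, rng):
        bm = BinMap(["G1", "G2"], 10)
        values = np.array([[0.5, -0.1, 0.02], [0.3, 0.2, -0.01]])
        feats = np.array([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        from binsight.explain import AttributionMatrix
        return AttributionMatrix(values=values, base_value=0.4,
                                 feature_values=feats,
                                 column_ids=["G1|bin0", "G1|bin9", "G2|bin3"],
                                 bin_map=bm, columns=[0, 9, 13])

    def test_interval_text_formatting(self, rng):
        rep = interval_report(self._attr(rng)).table
        assert rep.iloc[0].gene == "G1"
        assert rep.iloc[0].interval == "[0.00, 0.10)"
        closed = rep[rep.column_id == "G1|bin9"].iloc[0]
        assert closed.interval == "[0.90, 1.00]"

    def test_ranking_is_descending_mean_abs(self, rng):
        rep = interval_report(self._attr(rng)).table
        means = rep.mean_abs_attribution.to_numpy()
        assert np.all(np.diff(means) <= 1e-15)
        assert rep.iloc[0].column_id == "G1|bin0"  # mean |.| = 0.4

    def test_ranking_matches_independent_sort(self, rng):
        X = (rng.random((25, 6)) < 0.5).astype(float)
        y = (X[:, 2] > 0).astype(int)
        model = DecisionTreeClassifier(random_state=0).fit(X, y)
        attr = attribute(model, X[:10], X[10:20], engine="tree")
        rep = interval_report(attr).table
        expected = sorted(range(6),
                          key=lambda j: (-np.abs(attr.values[:, j]).mean(), j))
        got = [attr.column_ids.index(c) for c in rep.column_id]
        assert got == expected

    def test_top_n_bound(self, rng):
        with pytest.raises(ValueError, match="top_n"):
            interval_report(self._attr(rng), top_n=5)

    def test_planted_bin_reaches_top_of_report(self, planted_dataset):
        """A planted causal bin must surface in the top-5 intervals of a
        tree model trained on chi-square-selected range-features."""
        from binsight import (ExperimentConfig, binarize, minmax_normalize,
                              score_all, stratified_split)
        ds = planted_dataset
        b = binarize(minmax_normalize(ds.matrix), K=10)
        cols = score_all(b).top_k(20)
        X = b.values[:, cols].astype(float)
        y = ds.matrix.labels
        tr, te = stratified_split(y, 0.8, seed=0)
        model = RandomForestClassifier(n_estimators=50, random_state=0)
        model.fit(X[tr], y[tr])
        rng = np.random.default_rng(0)
        bg = X[tr][rng.choice(len(tr), size=40, replace=False)]
        attr = attribute(model, X[te], bg, engine="tree", bin_map=b.bin_map,
                         columns=[int(c) for c in cols])
        top5 = interval_report(attr, top_n=5).table.column_id.tolist()
        planted_ids = {b.bin_map[c].column_id for c in ds.truth_columns}
        assert planted_ids & set(top5)
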
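"""Shapley attribution: exactness, local accuracy, ranking, correlations."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from tastekit._treeshap import forest_shap, tree_shap
from tastekit.explain import (Attribution, feature_correlation, rank_features,
                              shapley_values)
from tastekit.descriptors import NormalizationParams
from tastekit.modelkit import ClassifierSpec, TastePredictor, train


def brute_force_shap(tree_arrays, x, n_features):
    """Subset-enumeration oracle with the cover-weighted conditional
    expectation (the same value function as the path-dependent recursion)."""
    cl, cr, feat, thr, val, cov = tree_arrays

    def cond_exp(node, coalition):
        if cl[node] < 0:
            return val[node]
        f = int(feat[node])
        if f in coalition:
            child = cl[node] if x[f] <= thr[node] else cr[node]
            return cond_exp(child, coalition)
        return (cov[cl[node]] * cond_exp(cl[node], coalition)
                + cov[cr[node]] * cond_exp(cr[node], coalition)) / cov[node]

    phi = np.zeros(n_features)
    for i in range(n_features):
        others = [f for f in range(n_features) if f != i]
        for r in range(n_features):
            for subset in combinations(others, r):
                w = (factorial(r) * factorial(n_features - r - 1)
                     / factorial(n_features))
                s = set(subset)
                phi[i] += w * (cond_exp(0, s | {i}) - cond_exp(0, s))
    return phi


def tree_arrays_of(estimator, class_index):
    t = estimator.tree_
    v = t.value.reshape(t.node_count, -1)
    out = v[:, class_index] / v.sum(axis=1)
    return (t.children_left, t.children_right, t.feature, t.threshold,
            out, t.weighted_n_node_samples)


def make_predictor(X, y, n_trees=10, family="random_forest", seed=0):
    names = [f"f{j}" for j in range(X.shape[1])]
    spec = ClassifierSpec(family, {"n_trees": n_trees}
                          if family == "random_forest" else {"C": 1.0,
                                                             "gamma": 0.5},
                          seed=seed)
    model = train(spec, X, y)
    params = NormalizationParams(minimum=pd.Series(0.0, index=names),
                                 maximum=pd.Series(1.0, index=names))
    order = tuple(dict.fromkeys(y))
    return TastePredictor(selected_features=names, normalization=params,
                          spec=spec, model=model, class_order=order)


class TestTreeShap:
    def test_constant_tree_gives_zero_attributions(self):
        X = np.random.default_rng(0).random((20, 2))
        y = np.array(["a"] * 20)
        predictor = make_predictor(X, y, n_trees=3)
        attr = shapley_values(predictor, X[:5], 0)
        np.testing.assert_array_equal(attr.values, np.zeros((5, 2)))
        assert attr.base_value == pytest.approx(1.0)

    def test_depth_one_tree_matches_two_orderings(self):
        """Depth-1 tree on 2 features: exact Shapley from the 2! orderings."""
        rng = np.random.default_rng(1)
        X = rng.random((60, 2))
        y = np.where(X[:, 0] > 0.5, "hot", "cold")
        clf = RandomForestClassifier(n_estimators=1, max_depth=1,
                                     random_state=0).fit(X, y)
        arrays = tree_arrays_of(clf.estimators_[0], 1)
        for s in range(4):
            expected = brute_force_shap(arrays, X[s], 2)
            got = tree_shap(*arrays, X[s], 2)
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_deeper_trees_match_subset_enumeration(self):
        rng = np.random.default_rng(2)
        X = rng.random((80, 3))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0.8, "hot", "cold")
        clf = RandomForestClassifier(n_estimators=4, max_depth=3,
                                     random_state=1).fit(X, y)
        for est in clf.estimators_:
            arrays = tree_arrays_of(est, 0)
            for s in range(3):
                np.testing.assert_allclose(
                    tree_shap(*arrays, X[s], 3),
                    brute_force_shap(arrays, X[s], 3), atol=1e-8)

    def test_local_accuracy(self):
        rng = np.random.default_rng(3)
        X = rng.random((100, 4))
        y = np.where(X[:, 0] > X[:, 1], "a", "b")
        clf = RandomForestClassifier(n_estimators=15, random_state=0).fit(X, y)
        phi, base = forest_shap(clf, X[:20], 1)
        pred = clf.predict_proba(X[:20])[:, 1]
        np.testing.assert_allclose(base + phi.sum(axis=1), pred, atol=1e-6)

    def test_duplicated_feature_symmetry(self):
        """Identical columns receive equal mean attribution."""
        rng = np.random.default_rng(4)
        base_col = rng.random(300)
        X = np.column_stack([base_col, base_col, rng.random(300)])
        y = np.where(base_col > 0.5, "a", "b")
        clf = RandomForestClassifier(n_estimators=40, random_state=0,
                                     max_features=1).fit(X, y)
        phi, _ = forest_shap(clf, X[:80], 0)
        totals = np.abs(phi).mean(axis=0)
        assert totals[0] == pytest.approx(totals[1], rel=0.15)

    def test_non_tree_model_falls_back_to_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.random((40, 2))
        y = np.where(X[:, 0] > 0.5, "a", "b")
        predictor = make_predictor(X, y, family="svm")
        attr = shapley_values(predictor, X[:3], 0, n_permutations=5, seed=0)
        assert attr.method == "permutation"
        assert attr.values.shape == (3, 2)


class TestRankFeatures:
    def _attr(self, values, names, cls):
        return Attribution(values=np.asarray(values, dtype=float),
                           base_value=0.0, feature_names=names,
                           class_name=cls, method="tree")

    def test_all_zero_gives_alphabetical_order(self):
        names = ["zeta", "alpha", "mid"]
        ranking = rank_features({
            "a": self._attr(np.zeros((4, 3)), names, "a"),
            "b": self._attr(np.zeros((4, 3)), names, "b")})
        assert list(ranking["feature"]) == ["alpha", "mid", "zeta"]
        assert (ranking["importance"] == 0).all()

    def test_single_active_feature_ranked_first(self):
        names = ["f0", "f1"]
        values = np.zeros((5, 2))
        values[:, 1] = 0.2
        ranking = rank_features({
            "a": self._attr(values, names, "a"),
            "b": self._attr(-values, names, "b")})
        assert ranking.loc[0, "feature"] == "f1"
        assert ranking.loc[0, "importance"] == pytest.approx(0.2)

    def test_hand_computed_means(self):
        names = ["x", "y"]
        a = self._attr([[0.1, -0.3], [0.3, 0.1]], names, "a")
        b = self._attr([[-0.2, 0.0], [0.0, 0.4]], names, "b")
        ranking = rank_features({"a": a, "b": b}).set_index("feature")
        assert ranking.loc["x", "importance"] == pytest.approx(
            (0.2 + 0.1) / 2)
        assert ranking.loc["y", "importance"] == pytest.approx(
            (0.2 + 0.2) / 2)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(30, 4))
        names = [f"f{j}" for j in range(4)]
        r1 = rank_features({"a": self._attr(values, names, "a")})
        r2 = rank_features({"a": self._attr(values[::-1], names, "a")})
        pd.testing.assert_frame_equal(r1, r2)

    def test_mismatched_features_raise(self):
        with pytest.raises(ValueError):
            rank_features({
                "a": self._attr(np.zeros((2, 2)), ["x", "y"], "a"),
                "b": self._attr(np.zeros((2, 2)), ["x", "z"], "b")})


class TestFeatureCorrelation:
    def test_exact_linear_relations(self):
        x = np.linspace(0, 1, 8)
        frame = pd.DataFrame({"x": x, "double": 2 * x, "neg": -x})
        corr = feature_correlation(frame)
        assert np.diag(corr.values) == pytest.approx(np.ones(3))
        assert corr.loc["x", "double"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)

    def test_five_point_toy_matches_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        corr = feature_correlation(pd.DataFrame({"x": x, "y": y}))
        cx, cy = x - x.mean(), y - y.mean()
        expected = (cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy))
        assert corr.loc["x", "y"] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_flagged_nan(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [5.0] * 3})
        corr = feature_correlation(frame)
        assert np.isnan(corr.loc["x", "const"])
        assert corr.loc["const", "const"] == 1.0

    def test_subset_and_errors(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        corr = feature_correlation(frame, ["a"])
        assert list(corr.columns) == ["a"]
        with pytest.raises(ValueError):
            feature_correlation(frame, ["missing"])
        with pytest.raises(ValueError):
            feature_correlation(frame.iloc[:1])
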
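"""Balancing, stratified CV, the metric suite, and training determinism."""

import numpy as np
import pytest

import tastekit.modelkit as mk
from tastekit.modelkit import (ClassifierSpec, balance_oversample,
                               compute_metrics, cross_validate,
                               model_complexity, predict_proba,
                               stratified_kfold, train)


def gaussian_clusters(n_per_class=50, n_features=30, n_informative=10,
                      shift=3.0, seed=0, classes=("bitter", "sweet",
                                                  "other", "umami")):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_per_class * len(classes), n_features))
    y = np.repeat(classes, n_per_class)
    for c, cls in enumerate(classes):
        X[y == cls, :n_informative] += c * shift
    return X, y


class TestBalanceOversample:
    def test_balanced_input_unchanged(self):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array(["a", "a", "b", "b"])
        X2, y2, syn = balance_oversample(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        assert not syn.any()

    def test_single_minority_sample_copied(self):
        X = np.arange(10.0).reshape(5, 2)
        y = np.array(["a", "a", "a", "a", "b"])
        X2, y2, syn = balance_oversample(X, y, seed=0)
        assert (y2 == "b").sum() == 4
        assert syn.sum() == 3
        np.testing.assert_array_equal(X2[syn], np.tile(X[4], (3, 1)))

    def test_copies_are_existing_members(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 3))
        y = np.array(["maj"] * 20 + ["min"] * 10)
        X2, y2, syn = balance_oversample(X, y, seed=2)
        originals = {tuple(row) for row in X[20:]}
        assert all(tuple(row) in originals for row in X2[syn])
        assert (y2[syn] == "min").all()

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_oversample(np.zeros((2, 1)), np.array(["a", "a"]))


class TestStratifiedKFold:
    def test_partition_and_pigeonhole(self):
        y = np.repeat(["a", "b", "c", "d"], 25)
        folds = stratified_kfold(y, k=10, seed=0)
        assert sorted(np.unique(folds)) == list(range(10))
        for f in range(10):
            assert (folds == f).sum() == 10
            for cls in "abcd":
                assert ((folds == f) & (y == cls)).sum() in (2, 3)

    def test_determinism_and_k_validation(self):
        y = np.repeat(["a", "b"], 10)
        np.testing.assert_array_equal(stratified_kfold(y, 5, seed=3),
                                      stratified_kfold(y, 5, seed=3))
        with pytest.raises(ValueError):
            stratified_kfold(y, k=1)
        with pytest.raises(ValueError):
            stratified_kfold(np.array(["a"] * 3 + ["b"] * 20), k=5)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array(["bitter", "sweet", "other", "umami"] * 3)
        probs = np.zeros((12, 4))
        order = ("bitter", "sweet", "other", "umami")
        for i, cls in enumerate(y):
            probs[i, order.index(cls)] = 1.0
        mv = compute_metrics(y, y, probs, order)
        assert mv.rates() == pytest.approx(np.ones(6))

    def test_f2_weights_recall_fourfold(self):
        """Binary toy with precision 0.5, recall 1.0 -> F2 = 5/6."""
        y_true = np.array(["a", "a", "b", "b"])
        y_pred = np.array(["a", "a", "a", "a"])
        probs = np.column_stack([np.ones(4), np.zeros(4)])
        mv = compute_metrics(y_true, y_pred, probs, ("a", "b"))
        f2_a = 5 * 0.5 * 1.0 / (4 * 0.5 + 1.0)
        assert mv.per_class.loc["a", "f2"] == pytest.approx(f2_a)
        assert mv.per_class.loc["a", "precision"] == pytest.approx(0.5)
        assert mv.per_class.loc["a", "recall"] == pytest.approx(1.0)

    def test_single_class_truth_flags_auc(self):
        y = np.array(["a", "a"])
        probs = np.column_stack([np.ones(2), np.zeros(2)])
        mv = compute_metrics(y, y, probs, ("a", "b"))
        assert mv.acc == 1.0
        assert np.isnan(mv.auc)
        assert "auc-undefined" in mv.flags

    def test_unknown_class_and_bad_probs_raise(self):
        with pytest.raises(ValueError):
            compute_metrics(["z"], ["a"], np.array([[1.0, 0.0]]), ("a", "b"))
        with pytest.raises(ValueError):
            compute_metrics(["a"], ["a"], np.array([[0.7, 0.6]]), ("a", "b"))

    def test_weighted_f1_bounded_by_per_class_f1(self):
        rng = np.random.default_rng(5)
        order = ("a", "b", "c")
        y_true = rng.choice(order, 60)
        y_pred = rng.choice(order, 60)
        probs = rng.dirichlet(np.ones(3), 60)
        mv = compute_metrics(y_true, y_pred, probs, order)
        per = mv.per_class["f1"]
        assert per.min() - 1e-12 <= mv.f1 <= per.max() + 1e-12

    def test_auc_extremes(self):
        """Scoring by the true indicator gives AUC 1; label-independent
        scores sit near 1/2."""
        rng = np.random.default_rng(6)
        y = rng.choice(["a", "b"], 200)
        ind = np.column_stack([(y == "a").astype(float),
                               (y == "b").astype(float)])
        assert compute_metrics(y, y, ind, ("a", "b")).auc == 1.0
        noise = rng.random(200)
        probs = np.column_stack([noise, 1 - noise])
        pred = np.where(noise > 0.5, "a", "b")
        assert compute_metrics(y, pred, probs, ("a", "b")).auc == \
            pytest.approx(0.5, abs=0.12)


class TestTrainPredict:
    def test_rf_95_trees_and_probability_rows(self):
        X, y = gaussian_clusters(n_per_class=15)
        spec = ClassifierSpec("random_forest", {"n_trees": 95}, seed=0)
        model = train(spec, X, y)
        assert model_complexity(model) == 95
        probs = predict_proba(model, X[:10])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_svm_probabilities(self):
        X, y = gaussian_clusters(n_per_class=12)
        spec = ClassifierSpec("svm", {"C": 1.0, "gamma": 0.1}, seed=0)
        model = train(spec, X, y)
        probs = predict_proba(model, X[:5])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert model_complexity(model) > 0

    def test_same_seed_identical_predictions(self):
        X, y = gaussian_clusters(n_per_class=15, shift=1.0)
        spec = ClassifierSpec("random_forest", {"n_trees": 20}, seed=9)
        p1 = predict_proba(train(spec, X, y), X)
        p2 = predict_proba(train(spec, X, y), X)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("random_forest", {"n_trees": 0})
        with pytest.raises(ValueError):
            ClassifierSpec("svm", {"C": -1.0})
        with pytest.raises(ValueError):
            ClassifierSpec("boosted_stump")


class TestCrossValidate:
    def test_separable_clusters_high_accuracy(self):
        """3-SD-separated Gaussian clusters are almost perfectly classifiable."""
        X, y = gaussian_clusters(n_per_class=50, shift=3.0, seed=1)
        spec = ClassifierSpec("random_forest", {"n_trees": 40}, seed=0)
        cv = cross_validate(spec, X, y, k=10, seed=0)
        assert cv.mean.acc >= 0.95
        assert len(cv.folds) == 10

    def test_shuffled_labels_at_chance(self):
        X, y = gaussian_clusters(n_per_class=50, shift=3.0, seed=1)
        rng = np.random.default_rng(2)
        cv = cross_validate(ClassifierSpec("random_forest",
                                           {"n_trees": 40}, seed=0),
                            X, rng.permutation(y), k=10, seed=0)
        assert cv.mean.acc == pytest.approx(0.25, abs=0.10)

    def test_oversampling_restricted_to_training_portion(self, monkeypatch):
        """The rows handed to the oversampler are exactly the fold's training
        portion, so synthetic copies cannot reach a validation fold."""
        X, y = gaussian_clusters(n_per_class=12, n_features=1,
                                 n_informative=1, seed=3)
        X[:, 0] = np.arange(len(y))  # unique row fingerprints
        calls = []
        original = mk.balance_oversample

        def spy(Xa, ya, seed=0):
            calls.append(np.asarray(Xa)[:, 0].copy())
            return original(Xa, ya, seed)

        monkeypatch.setattr(mk, "balance_oversample", spy)
        k = 4
        cv = cross_validate(ClassifierSpec("random_forest",
                                           {"n_trees": 5}, seed=0),
                            X, y, k=k, seed=11)
        folds = stratified_kfold(y, k=k, seed=11)
        assert len(calls) == k
        for f in range(k):
            val_rows = set(X[folds == f, 0])
            assert val_rows.isdisjoint(calls[f])
        assert len(cv.folds) == k
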
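"""Classifiers: separability, architecture contracts, grid search."""

import numpy as np
import pytest

from crabspec import (
    ClassifierSpec,
    default_spec,
    grid_search,
    predict,
    predict_proba,
    train_bp,
    train_cnn,
    train_svm,
)
from crabspec.models import _NumpyCNN


@pytest.fixture(scope="module")
def separable_3class():
    rng = np.random.default_rng(0)
    n = 40
    centers = [np.zeros(10), np.r_[np.full(5, 3.0), np.zeros(5)], np.r_[np.zeros(5), np.full(5, 3.0)]]
    X = np.vstack([rng.normal(0, 0.3, (n, 10)) + c for c in centers])
    labels = np.array(["WL"] * n + ["TL"] * n + ["HL"] * n)
    return X, labels


class TestSpec:
    def test_defaults_filled_per_family(self):
        spec = default_spec("SVM")
        assert spec.hyperparameters == {"C": 1.0, "gamma": 0.5, "kernel": "rbf"}
        assert default_spec("CNN").hyperparameters["epochs"] == 299

    def test_unknown_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("SVM", {"epochs": 3})
        with pytest.raises(ValueError):
            ClassifierSpec("BP", {"learning_rate": -1.0})


class TestSVM:
    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.2, (30, 2)), rng.normal(4, 0.2, (30, 2))])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        clf = train_svm(X, labels)
        assert (predict(clf, X) == labels).mean() == 1.0

    def test_xor_pattern_with_rbf(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        labels = np.array(["p", "q", "q", "p"])
        clf = train_svm(X, labels, default_spec("SVM", gamma=2.0, C=10.0))
        assert (predict(clf, X) == labels).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.random.default_rng(0).standard_normal((5, 2)), ["a"] * 5)


class TestBP:
    def test_separable_data_trained_to_high_accuracy(self, separable_3class):
        X, labels = separable_3class
        clf = train_bp(X, labels)
        assert (predict(clf, X) == labels).mean() >= 0.95

    def test_seeded_weights_identical(self, separable_3class):
        X, labels = separable_3class
        spec = default_spec("BP", iterations=200)
        a = train_bp(X, labels, spec)
        b = train_bp(X, labels, spec)
        assert all(np.array_equal(wa, wb) for wa, wb in zip(a.model.coefs_, b.model.coefs_))

    def test_hidden_architecture_is_6_3(self, separable_3class):
        X, labels = separable_3class
        clf = train_bp(X, labels, default_spec("BP", iterations=50))
        assert clf.model.hidden_layer_sizes == (6, 3)
        # weight matrices: input->6, 6->3, 3->K
        shapes = [w.shape for w in clf.model.coefs_]
        assert shapes == [(10, 6), (6, 3), (3, 3)]

    def test_probabilities_sum_to_one(self, separable_3class):
        X, labels = separable_3class
        clf = train_bp(X, labels, default_spec("BP", iterations=100))
        probs = predict_proba(clf, X[:7])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestCNN:
    def test_shape_chain_for_29_inputs(self):
        net = _NumpyCNN(input_dim=29, n_classes=3, seed=0)
        assert net.shape_chain() == [29, 27, 25, 12, 192, 6, 3]

    def test_too_small_input_rejected_before_training(self):
        with pytest.raises(ValueError, match="input_dim"):
            _NumpyCNN(input_dim=7, n_classes=3, seed=0)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 15))
        labels = np.array(["a", "b"] * 10)
        clf = train_cnn(X, labels, default_spec("CNN", epochs=3))
        probs = predict_proba(clf, X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_learns_separable_classes(self):
        rng = np.random.default_rng(3)
        n = 30
        X = np.vstack([rng.normal(m, 0.3, (n, 20)) for m in (0.0, 1.5, -1.5)])
        labels = np.array(["a"] * n + ["b"] * n + ["c"] * n)
        clf = train_cnn(X, labels, default_spec("CNN", epochs=40))
        assert (predict(clf, X) == labels).mean() >= 0.95

    def test_constant_input_collapses_to_majority(self):
        X = np.ones((30, 12))
        labels = np.array(["a"] * 20 + ["b"] * 10)
        clf = train_cnn(X, labels, default_spec("CNN", epochs=15))
        preds = predict(clf, X)
        assert (preds == "a").all()

    def test_seeded_training_identical(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((16, 10))
        labels = np.array(["a", "b"] * 8)
        spec = default_spec("CNN", epochs=5)
        a = train_cnn(X, labels, spec)
        b = train_cnn(X, labels, spec)
        assert all(np.array_equal(a.model.params[k], b.model.params[k]) for k in a.model.params)

    def test_numerical_gradients_match_backprop(self):
        rng = np.random.default_rng(5)
        net = _NumpyCNN(input_dim=12, n_classes=3, seed=1)
        X = rng.standard_normal((5, 12))
        y_idx = np.array([0, 1, 2, 1, 0])
        onehot = np.zeros((5, 3))
        onehot[np.arange(5), y_idx] = 1.0
        probs, cache = net._forward(X)
        grads = net._backward(probs, onehot, cache)

        def loss():
            p, _ = net._forward(X)
            return -np.mean(np.log(p[np.arange(5), y_idx]))

        eps = 1e-6
        for key in net.params:
            w = net.params[key]
            idx = tuple(0 for _ in w.shape)
            w[idx] += eps
            lp = loss()
            w[idx] -= 2 * eps
            lm = loss()
            w[idx] += eps
            numeric = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestPredict:
    def test_memorizing_model_returns_training_labels(self, separable_3class):
        X, labels = separable_3class
        clf = train_svm(X, labels, default_spec("SVM", C=100.0, gamma=1.0))
        assert (predict(clf, X) == labels).all()

    def test_empty_input_gives_empty_output(self, separable_3class):
        X, labels = separable_3class
        clf = train_svm(X, labels)
        assert predict(clf, np.empty((0, X.shape[1]))).size == 0

    def test_probability_argmax_consistent_with_labels(self, separable_3class):
        X, labels = separable_3class
        clf = train_bp(X, labels, default_spec("BP", iterations=300))
        probs = predict_proba(clf, X)
        by_probs = np.asarray(clf.class_order)[probs.argmax(axis=1)]
        assert (by_probs == predict(clf, X)).all()

    def test_dimension_mismatch_rejected(self, separable_3class):
        X, labels = separable_3class
        clf = train_svm(X, labels)
        with pytest.raises(ValueError, match="features"):
            predict(clf, np.zeros((3, X.shape[1] + 1)))


class TestGridSearch:
    def test_singleton_grid_returned(self, separable_3class):
        X, labels = separable_3class
        spec = grid_search("SVM", {"C": [2.0]}, X, labels, folds=3, seed=0)
        assert spec.hyperparameters["C"] == 2.0

    def test_picks_good_over_degenerate_option(self, separable_3class):
        X, labels = separable_3class
        spec = grid_search(
            "SVM", {"gamma": [0.5, 1e-9]}, X, labels, folds=3, seed=0
        )
        assert spec.hyperparameters["gamma"] == 0.5

    def test_combination_count_is_exhaustive(self, separable_3class):
        X, labels = separable_3class
        _, audit = grid_search(
            "SVM",
            {"C": [0.5, 1.0, 2.0], "gamma": [0.1, 0.5]},
            X,
            labels,
            folds=3,
            seed=0,
            return_audit=True,
        )
        assert audit["n_combinations"] == 6

    def test_empty_grid_rejected(self, separable_3class):
        X, labels = separable_3class
        with pytest.raises(ValueError):
            grid_search("SVM", {}, X, labels)
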
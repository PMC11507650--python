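"""Origin classifiers on selected wavelengths: SVM, BP net, 1-D CNN.

The SVM (RBF kernel, one-vs-one multiclass) and the small
backpropagation network (input -> 6 -> 3 -> K, cross-entropy) are backed
by scikit-learn; the 1-D convolutional network
(Conv(8, k=3) -> Conv(16, k=3) -> MaxPool(2) -> Dense(6) -> softmax(K))
is implemented here in numpy with Adam updates, since the architecture
is specific to short wavelength-selected spectra.  All training is
seed-deterministic.  Grid search evaluates every hyperparameter
combination by k-fold cross-validated accuracy on the training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "default_spec",
    "train_svm",
    "train_bp",
    "train_cnn",
    "train_classifier",
    "grid_search",
    "predict",
    "predict_proba",
]

_FAMILIES = ("SVM", "BP", "CNN")

#: Grid-search optima used as family defaults.
_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "SVM": {"C": 1.0, "gamma": 0.5, "kernel": "rbf"},
    "BP": {"iterations": 2500, "learning_rate": 0.003, "stopping_error": 5e-6},
    "CNN": {"epochs": 299, "batch_size": 4, "initial_learning_rate": 0.0001},
}

_ALLOWED_KEYS = {k: set(v) for k, v in _DEFAULT_HYPERPARAMETERS.items()}


@dataclass(frozen=True)
class ClassifierSpec:
    """Family + hyperparameters + seed of one classifier configuration."""

    family: str
    hyperparameters: Mapping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        extra = set(self.hyperparameters) - _ALLOWED_KEYS[self.family]
        if extra:
            raise ValueError(f"unknown {self.family} hyperparameters: {sorted(extra)}")
        hp = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        hp.update(self.hyperparameters)
        for key, value in hp.items():
            if key != "kernel" and value <= 0:
                raise ValueError(f"{self.family} hyperparameter {key} must be positive")
        object.__setattr__(self, "hyperparameters", hp)


def default_spec(family: str, seed: int = 0, **overrides) -> ClassifierSpec:
    return ClassifierSpec(family=family, hyperparameters=overrides, seed=seed)


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    class_order: list
    model: object = field(repr=False)
    input_dim: int


def _check_training_input(X: np.ndarray, labels: np.ndarray):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("X and labels must be row-aligned")
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least two classes")
    return X, labels


def _resolve_class_order(labels: np.ndarray, class_order: Sequence | None) -> list:
    if class_order is None:
        return [c for c in np.unique(labels)]
    order = list(class_order)
    unknown = set(np.unique(labels)) - set(order)
    if unknown:
        raise ValueError(f"labels {sorted(map(str, unknown))} not in class_order")
    return order


def train_svm(
    X_sel: np.ndarray,
    labels: Sequence,
    spec: ClassifierSpec | None = None,
    class_order: Sequence | None = None,
) -> TrainedClassifier:
    """RBF-kernel SVM, one-vs-one multiclass reduction."""
    X, labels = _check_training_input(X_sel, np.asarray(labels))
    spec = spec or default_spec("SVM")
    hp = spec.hyperparameters
    clf = SVC(C=hp["C"], gamma=hp["gamma"], kernel=hp["kernel"])
    clf.fit(X, labels)
    return TrainedClassifier(
        spec=spec,
        class_order=_resolve_class_order(labels, class_order),
        model=clf,
        input_dim=X.shape[1],
    )


def train_bp(
    X_sel: np.ndarray,
    labels: Sequence,
    spec: ClassifierSpec | None = None,
    class_order: Sequence | None = None,
) -> TrainedClassifier:
    """Feed-forward net input -> 6 -> 3 -> K trained by backpropagation.

    Gradient descent on the cross-entropy loss; training stops at the
    configured iteration budget or once the loss stops improving by more
    than the stopping error.
    """
    X, labels = _check_training_input(X_sel, np.asarray(labels))
    spec = spec or default_spec("BP")
    hp = spec.hyperparameters
    clf = MLPClassifier(
        hidden_layer_sizes=(6, 3),
        activation="relu",
        solver="sgd",
        learning_rate_init=hp["learning_rate"],
        max_iter=int(hp["iterations"]),
        tol=hp["stopping_error"],
        n_iter_no_change=10,
        alpha=0.0,
        batch_size=min(32, X.shape[0]),
        random_state=spec.seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, labels)
    if not np.isfinite(clf.loss_):
        raise RuntimeError(
            f"BP training diverged: loss={clf.loss_} after {clf.n_iter_} iterations "
            f"at learning rate {hp['learning_rate']}"
        )
    return TrainedClassifier(
        spec=spec,
        class_order=_resolve_class_order(labels, class_order),
        model=clf,
        input_dim=X.shape[1],
    )


class _NumpyCNN:
    """1-D CNN: Conv(8,k3)+ReLU -> Conv(16,k3)+ReLU -> MaxPool(2) ->
    Dense(6)+ReLU -> Dense(K)+softmax, trained with Adam on cross-entropy.
    """

    K1, K2 = 3, 3
    C1, C2 = 8, 16
    DENSE = 6

    def __init__(self, input_dim: int, n_classes: int, seed: int):
        if input_dim < 8:
            raise ValueError(
                f"CNN needs input_dim >= 8 (two k=3 convolutions + pooling), got {input_dim}"
            )
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.pooled_len = (input_dim - 4) // 2
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params = {
            "W1": he((self.C1, self.K1), self.K1),
            "b1": np.zeros(self.C1),
            "W2": he((self.C2, self.K2, self.C1), self.K2 * self.C1),
            "b2": np.zeros(self.C2),
            "W3": he((self.pooled_len * self.C2, self.DENSE), self.pooled_len * self.C2),
            "b3": np.zeros(self.DENSE),
            "W4": he((self.DENSE, n_classes), self.DENSE),
            "b4": np.zeros(n_classes),
        }
        self._rng = rng
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # layer output lengths: L -> L-2 -> L-4 -> (L-4)//2 -> 16*(L-4)//2 -> 6 -> K
    def shape_chain(self) -> list[int]:
        L = self.input_dim
        return [L, L - 2, L - 4, self.pooled_len, self.pooled_len * self.C2, self.DENSE, self.n_classes]

    def _forward(self, X: np.ndarray):
        p = self.params
        win1 = sliding_window_view(X, self.K1, axis=1)  # (B, L-2, 3)
        z1 = np.einsum("blk,ok->blo", win1, p["W1"]) + p["b1"]
        a1 = np.maximum(z1, 0.0)
        win2 = sliding_window_view(a1, self.K2, axis=1)  # (B, L-4, C1, 3)
        z2 = np.einsum("blck,okc->blo", win2, p["W2"]) + p["b2"]
        a2 = np.maximum(z2, 0.0)
        P = self.pooled_len
        pairs = a2[:, : 2 * P].reshape(X.shape[0], P, 2, self.C2)
        pool_arg = pairs.argmax(axis=2)
        pooled = np.take_along_axis(pairs, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(X.shape[0], -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        z4 = a3 @ p["W4"] + p["b4"]
        z4 = z4 - z4.max(axis=1, keepdims=True)
        e = np.exp(z4)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = (X, win1, z1, a1, win2, z2, a2, pairs, pool_arg, flat, z3, a3)
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if X.shape[0] == 0:
            return np.zeros((0, self.n_classes))
        probs, _ = self._forward(np.asarray(X, dtype=float))
        return probs

    def _backward(self, probs: np.ndarray, onehot: np.ndarray, cache):
        p = self.params
        X, win1, z1, a1, win2, z2, a2, pairs, pool_arg, flat, z3, a3 = cache
        B = X.shape[0]
        g = {}
        dz4 = (probs - onehot) / B
        g["W4"] = a3.T @ dz4
        g["b4"] = dz4.sum(axis=0)
        dz3 = (dz4 @ p["W4"].T) * (z3 > 0)
        g["W3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dpooled = (dz3 @ p["W3"].T).reshape(B, self.pooled_len, self.C2)
        dpairs = np.zeros_like(pairs)
        np.put_along_axis(dpairs, pool_arg[:, :, None, :], dpooled[:, :, None, :], axis=2)
        da2 = np.zeros_like(a2)
        da2[:, : 2 * self.pooled_len] = dpairs.reshape(B, 2 * self.pooled_len, self.C2)
        dz2 = da2 * (z2 > 0)
        g["W2"] = np.einsum("blck,blo->okc", win2, dz2)
        g["b2"] = dz2.sum(axis=(0, 1))
        dz2p = np.pad(dz2, ((0, 0), (self.K2 - 1, self.K2 - 1), (0, 0)))
        winb = sliding_window_view(dz2p, self.K2, axis=1)  # (B, L-2, C2, 3)
        W2flip = p["W2"][:, ::-1, :]  # (C2, 3, C1)
        da1 = np.einsum("blok,okc->blc", winb, W2flip)
        dz1 = da1 * (z1 > 0)
        g["W1"] = np.einsum("blk,blo->ok", win1, dz1)
        g["b1"] = dz1.sum(axis=(0, 1))
        return g

    def _adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(self, X: np.ndarray, y_idx: np.ndarray, epochs: int, batch_size: int, lr: float):
        n = X.shape[0]
        onehot = np.zeros((n, self.n_classes))
        onehot[np.arange(n), y_idx] = 1.0
        for epoch in range(epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, batch_size):
                batch = order[start : start + batch_size]
                probs, cache = self._forward(X[batch])
                loss = -np.mean(
                    np.log(np.clip(probs[np.arange(batch.size), y_idx[batch]], 1e-12, None))
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"CNN training diverged (loss={loss}) at epoch {epoch}"
                    )
                grads = self._backward(probs, onehot[batch], cache)
                self._adam_step(grads, lr)
        return self


def train_cnn(
    X_sel: np.ndarray,
    labels: Sequence,
    spec: ClassifierSpec | None = None,
    class_order: Sequence | None = None,
) -> TrainedClassifier:
    """1-D convolutional network on the selected-wavelength vectors."""
    X, labels = _check_training_input(X_sel, np.asarray(labels))
    spec = spec or default_spec("CNN")
    hp = spec.hyperparameters
    order = _resolve_class_order(labels, class_order)
    lut = {c: i for i, c in enumerate(order)}
    y_idx = np.asarray([lut[l] for l in labels])
    net = _NumpyCNN(input_dim=X.shape[1], n_classes=len(order), seed=spec.seed)
    net.fit(
        X,
        y_idx,
        epochs=int(hp["epochs"]),
        batch_size=int(hp["batch_size"]),
        lr=hp["initial_learning_rate"],
    )
    return TrainedClassifier(spec=spec, class_order=order, model=net, input_dim=X.shape[1])


_TRAINERS = {"SVM": train_svm, "BP": train_bp, "CNN": train_cnn}


def train_classifier(
    X_sel: np.ndarray,
    labels: Sequence,
    spec: ClassifierSpec,
    class_order: Sequence | None = None,
) -> TrainedClassifier:
    return _TRAINERS[spec.family](X_sel, labels, spec, class_order)


def predict(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Predicted labels, one per row, drawn from clf.class_order."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        X = X.reshape(0, clf.input_dim) if X.ndim < 2 else X
    X = np.atleast_2d(X)
    if X.shape[1] != clf.input_dim:
        raise ValueError(f"expected {clf.input_dim} features, got {X.shape[1]}")
    if X.shape[0] == 0:
        return np.asarray([], dtype=np.asarray(clf.class_order).dtype)
    if isinstance(clf.model, _NumpyCNN):
        probs = clf.model.predict_proba(X)
        return np.asarray(clf.class_order)[probs.argmax(axis=1)]
    return clf.model.predict(X)


def predict_proba(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray | None:
    """Per-class probabilities in clf.class_order, or None (SVM)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(clf.model, _NumpyCNN):
        return clf.model.predict_proba(X)
    if isinstance(clf.model, MLPClassifier):
        probs = clf.model.predict_proba(X)
        cols = [list(clf.model.classes_).index(c) for c in clf.class_order]
        return probs[:, cols]
    return None


def grid_search(
    family: str,
    grid: Mapping[str, Sequence],
    X_train: np.ndarray,
    labels: Sequence,
    folds: int = 5,
    seed: int = 0,
    return_audit: bool = False,
):
    """Exhaustive hyperparameter search by k-fold CV accuracy.

    Every combination in the Cartesian product of ``grid`` values is
    evaluated; ties break toward the earlier combination in grid order.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    X, labels = _check_training_input(X_train, np.asarray(labels))
    keys = list(grid)
    combos = list(itertools.product(*(grid[k] for k in keys)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, labels))
    accuracies = []
    for combo in combos:
        hp = dict(zip(keys, combo))
        spec = ClassifierSpec(family=family, hyperparameters=hp, seed=seed)
        correct = 0
        for train_rows, val_rows in splits:
            clf = train_classifier(X[train_rows], labels[train_rows], spec)
            correct += int((predict(clf, X[val_rows]) == labels[val_rows]).sum())
        accuracies.append(correct / X.shape[0])
    best = int(np.argmax(accuracies))  # first maximum wins ties
    best_spec = ClassifierSpec(family=family, hyperparameters=dict(zip(keys, combos[best])), seed=seed)
    if return_audit:
        audit = {
            "n_combinations": len(combos),
            "combinations": [dict(zip(keys, c)) for c in combos],
            "cv_accuracy": accuracies,
        }
        return best_spec, audit
    return best_spec
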
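"""Classifiers behind a single train / predict-probability contract.

The headline model is a conic multilayer perceptron — hidden widths shrink
512 -> 128 -> 32 — with ReLU hidden activations, a sigmoid output unit and
binary cross-entropy loss, trained by minibatch Adam. It is implemented
here directly on NumPy. The five comparison baselines are a shallow neural
network (one hidden layer with heavy dropout, same NumPy engine) and
scikit-learn's KNN, linear-kernel SVM, random forest and gradient boosting
classifiers with fixed hyperparameters.

All models see min-max scaled features (fit on training rows only): the
design matrix mixes binary indicators, substructure counts and
physicochemical descriptors whose raw scales are not commensurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "TrainedModel",
    "relu",
    "sigmoid",
    "binary_cross_entropy",
    "train",
    "predict_proba",
    "predict_label",
]

MODEL_KINDS = ("syndeep_mlp", "snn", "knn", "svm", "rf", "gbc")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "syndeep_mlp": dict(hidden=(512, 128, 32), learning_rate=1e-2, epochs=100,
                        batch_size=128, dropout=0.0),
    "snn": dict(hidden=(64,), learning_rate=1e-2, epochs=300, batch_size=128,
                dropout=0.8),
    "knn": dict(n_neighbors=4, metric="minkowski", p=2),
    "svm": dict(kernel="linear", degree=3, cache_size=200),
    "rf": dict(max_depth=4, n_estimators=10),
    "gbc": dict(max_depth=3, n_estimators=100),
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier kind plus its hyperparameters and RNG seed.

    Unspecified hyperparameters take the published defaults for the kind;
    unknown names are rejected.
    """

    kind: str
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; one of {MODEL_KINDS}")
        unknown = set(self.hyperparams) - set(_DEFAULTS[self.kind])
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")

    def resolved(self) -> dict[str, Any]:
        return {**_DEFAULTS[self.kind], **self.hyperparams}


@dataclass
class TrainedModel:
    spec: ModelSpec
    scaler: MinMaxScaler
    estimator: Any            # _NumpyMLP or a fitted sklearn classifier
    loss_trace: list[float]   # per-epoch mean training loss (MLP kinds only)
    n_features: int


def relu(x):
    """Rectified linear unit: x if x >= 0 else 0 (elementwise on arrays)."""
    return np.maximum(x, 0)


def sigmoid(x):
    """Logistic function 1 / (1 + e^-x), numerically stable for large |x|."""
    arr = np.asarray(x, dtype=float)
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ex = np.exp(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if isinstance(x, np.ndarray) else float(out) if out.ndim == 0 else out


def binary_cross_entropy(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mean binary cross-entropy L = -(1/N) sum y*log(s) + (1-y)*log(1-s)."""
    y = np.asarray(y_true, dtype=float)
    s = np.clip(np.asarray(scores, dtype=float), 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


class _NumpyMLP:
    """Fully-connected net with ReLU hidden layers and one sigmoid output,
    trained on binary cross-entropy with minibatch Adam.

    Supports inverted dropout on hidden activations (used by the shallow
    baseline). He-initialized; training order and init are driven by one
    Generator so equal seeds give bit-identical parameters.
    """

    def __init__(self, hidden, learning_rate, epochs, batch_size, dropout, seed):
        self.hidden = tuple(hidden)
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.seed = seed
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self.loss_trace: list[float] = []

    def _init_params(self, n_in, rng):
        sizes = (n_in, *self.hidden, 1)
        self.weights, self.biases = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            self.biases.append(np.zeros(b))

    def _forward(self, X, rng=None):
        """Returns hidden activations and output logits; applies dropout
        when an rng is supplied (training mode)."""
        acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = relu(h @ W + b)
            if rng is not None and self.dropout > 0:
                keep = 1.0 - self.dropout
                mask = rng.random(h.shape) < keep
                h = h * mask / keep
            acts.append(h)
        logits = acts[-1] @ self.weights[-1] + self.biases[-1]
        return acts, logits.ravel()

    def fit(self, X, y):
        rng = np.random.default_rng(self.seed)
        n, d = X.shape
        self._init_params(d, rng)
        m_w = [np.zeros_like(W) for W in self.weights]
        v_w = [np.zeros_like(W) for W in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                Xb, yb = X[idx], y[idx]
                acts, logits = self._forward(Xb, rng=rng)
                probs = sigmoid(logits)
                epoch_losses.append(binary_cross_entropy(yb, probs) * len(idx))
                # d(BCE)/d(logit) for a sigmoid output is simply p - y
                delta = ((probs - yb) / len(idx))[:, None]
                grads_w, grads_b = [None] * len(self.weights), [None] * len(self.biases)
                for layer in range(len(self.weights) - 1, -1, -1):
                    grads_w[layer] = acts[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
                step += 1
                for layer in range(len(self.weights)):
                    for p, g, m, v in (
                        (self.weights, grads_w, m_w, v_w),
                        (self.biases, grads_b, m_b, v_b),
                    ):
                        m[layer] = beta1 * m[layer] + (1 - beta1) * g[layer]
                        v[layer] = beta2 * v[layer] + (1 - beta2) * g[layer] ** 2
                        m_hat = m[layer] / (1 - beta1 ** step)
                        v_hat = v[layer] / (1 - beta2 ** step)
                        p[layer] = p[layer] - self.learning_rate * m_hat / (
                            np.sqrt(v_hat) + eps
                        )
            self.loss_trace.append(float(np.sum(epoch_losses) / n))
        return self

    def predict_proba_1d(self, X):
        _, logits = self._forward(X, rng=None)
        return sigmoid(logits)


def _make_sklearn(spec: ModelSpec):
    h = spec.resolved()
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=h["n_neighbors"], metric=h["metric"],
                                    p=h["p"])
    if spec.kind == "svm":
        # margin mapped through a sigmoid supplies the probability output;
        # the 0.5 threshold then coincides with the SVM's own decision rule
        return SVC(kernel=h["kernel"], degree=h["degree"], cache_size=h["cache_size"],
                   random_state=spec.seed)
    if spec.kind == "rf":
        return RandomForestClassifier(max_depth=h["max_depth"],
                                      n_estimators=h["n_estimators"],
                                      random_state=spec.seed)
    if spec.kind == "gbc":
        return GradientBoostingClassifier(max_depth=h["max_depth"],
                                          n_estimators=h["n_estimators"],
                                          random_state=spec.seed)
    raise AssertionError(spec.kind)


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
          seed: int | None = None) -> TrainedModel:
    """Fit a classifier on (X, y); returns the fitted model with its scaler.

    Min-max scaling is fit here, on these rows only, so cross-validation
    callers get fold-isolated scaling for free. ``seed`` overrides the
    spec's seed for this fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X rows ({X.shape}) must match y length ({y.shape})")
    if np.isnan(X).any():
        raise ValueError("design matrix contains NaN")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if seed is None:
        seed = spec.seed

    scaler = MinMaxScaler().fit(X)
    Xs = scaler.transform(X)
    if spec.kind in ("syndeep_mlp", "snn"):
        h = spec.resolved()
        mlp = _NumpyMLP(hidden=h["hidden"], learning_rate=h["learning_rate"],
                        epochs=h["epochs"], batch_size=h["batch_size"],
                        dropout=h["dropout"], seed=seed)
        mlp.fit(Xs, y.astype(float))
        return TrainedModel(spec, scaler, mlp, mlp.loss_trace, X.shape[1])
    est = _make_sklearn(ModelSpec(spec.kind, spec.hyperparams, seed))
    est.fit(Xs, y)
    return TrainedModel(spec, scaler, est, [], X.shape[1])


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Probability of the synergistic class for each row of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model was trained on {model.n_features}"
        )
    Xs = model.scaler.transform(X)
    if isinstance(model.estimator, _NumpyMLP):
        return model.estimator.predict_proba_1d(Xs)
    if isinstance(model.estimator, SVC):
        margin = model.estimator.decision_function(Xs)
        if model.estimator.classes_[1] != 1:
            margin = -margin
        return sigmoid(margin)
    proba = model.estimator.predict_proba(Xs)
    pos = list(model.estimator.classes_).index(1)
    return proba[:, pos]


def predict_label(model: TrainedModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels at the decision threshold (0.5: classes are balanced)."""
    return (predict_proba(model, X) >= threshold).astype(int)
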
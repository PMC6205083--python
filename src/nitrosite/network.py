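"""A fully-connected feed-forward classifier trained with mini-batch
momentum SGD, implemented in numpy.

The default architecture is the eight-layer site classifier: an input
layer, six dense+ReLU hidden layers (256, 128, 64, 32, 16, 8 units) and a
two-unit softmax output.  Inverted dropout acts on the first three hidden
layers during training.  The loss is mean categorical cross-entropy plus
L1 and L2 penalties over all weights and biases; parameters are updated
with classical momentum (velocity v ← m·v − η·∇, θ ← θ + v).

The same class, with different ``hidden_sizes``, also serves as the small
probe MLP used by the layer-abstraction analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

LOG_CLAMP = 1e-12


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


def relu(x):
    """Rectified linear activation, elementwise max(0, x)."""
    return np.maximum(0.0, x)


def softmax(y):
    """Overflow-safe softmax along the last axis."""
    y = np.asarray(y, dtype=float)
    shifted = y - np.max(y, axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=-1, keepdims=True)


@dataclass
class NetworkConfig:
    """Hyperparameters of the eight-layer site classifier.

    ``hidden_sizes`` must name exactly six hidden layers (layers 2-7 of the
    eight-layer architecture); dropout applies to the first three of them.
    Batch size defaults: 30 for nitration models, 50 for S-nitrosylation.
    """

    input_dim: int | None = None
    hidden_sizes: tuple[int, ...] = (256, 128, 64, 32, 16, 8)
    output_dim: int = 2
    dropout_rates: tuple[float, ...] = (0.5, 0.5, 0.5)
    learning_rate: float = 0.01
    momentum: float = 0.9
    l1: float = 1e-5
    l2: float = 1e-4
    batch_size: int = 30
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_sizes) != 6:
            raise ValueError("the site classifier has exactly 6 hidden layers")
        if len(self.dropout_rates) > 3:
            raise ValueError("dropout applies to the first three hidden layers only")
        self.validate_common()

    def validate_common(self):
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not all(0.0 <= r < 1.0 for r in self.dropout_rates):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("regularization coefficients must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be positive")

    def classifier(self) -> "DenseNetworkClassifier":
        return DenseNetworkClassifier(
            hidden_sizes=self.hidden_sizes,
            dropout_rates=self.dropout_rates,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            l1=self.l1,
            l2=self.l2,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
        )


class DenseNetworkClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward dense network with ReLU hidden layers and softmax output.

    Parameters mirror :class:`NetworkConfig`; any number of hidden layers is
    accepted so the same trainer drives both the eight-layer site model and
    the four-layer probe MLP.
    """

    def __init__(
        self,
        hidden_sizes=(256, 128, 64, 32, 16, 8),
        dropout_rates=(0.5, 0.5, 0.5),
        learning_rate=0.01,
        momentum=0.9,
        l1=1e-5,
        l2=1e-4,
        batch_size=30,
        epochs=100,
        seed=0,
    ):
        self.hidden_sizes = hidden_sizes
        self.dropout_rates = dropout_rates
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.l1 = l1
        self.l2 = l2
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    # -- construction -------------------------------------------------------

    def _init_params(self, input_dim: int, rng: np.random.Generator):
        sizes = [input_dim, *self.hidden_sizes, 2]
        self.coefs_ = [
            rng.normal(0.0, 1.0 / np.sqrt(sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.intercepts_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _seed_entropy(self) -> int:
        return abs(int(self.seed)) % (2**31)

    # -- forward / backward -------------------------------------------------

    def _forward(self, X, masks=None):
        """Return (hidden activations list, output probabilities).

        ``masks`` are inverted-dropout masks for the leading hidden layers
        (None for inference mode).
        """
        a = X
        hidden = []
        n_hidden = len(self.coefs_) - 1
        for layer in range(n_hidden):
            a = relu(a @ self.coefs_[layer] + self.intercepts_[layer])
            if masks is not None and layer < len(masks) and masks[layer] is not None:
                a = a * masks[layer]
            hidden.append(a)
        logits = a @ self.coefs_[-1] + self.intercepts_[-1]
        return hidden, softmax(logits)

    def _regularization(self) -> float:
        total = 0.0
        for W, b in zip(self.coefs_, self.intercepts_):
            total += self.l1 * (np.abs(W).sum() + np.abs(b).sum())
            total += self.l2 * ((W**2).sum() + (b**2).sum())
        return total

    def loss(self, X, Y_onehot, masks=None) -> float:
        """Mean categorical cross-entropy plus L1/L2 penalties."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y_onehot, dtype=float)
        if len(X) == 0:
            raise ValueError("empty batch")
        _, probs = self._forward(X, masks)
        ce = -np.mean(np.sum(Y * np.log(np.maximum(probs, LOG_CLAMP)), axis=1))
        return float(ce + self._regularization())

    def loss_and_gradients(self, X, Y_onehot, masks=None):
        """Loss plus analytic gradients for every weight matrix and bias.

        Used both by the trainer and by finite-difference verification.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y_onehot, dtype=float)
        n = len(X)
        if n == 0:
            raise ValueError("empty batch")
        hidden, probs = self._forward(X, masks)
        ce = -np.mean(np.sum(Y * np.log(np.maximum(probs, LOG_CLAMP)), axis=1))
        loss = ce + self._regularization()

        grads_W = [None] * len(self.coefs_)
        grads_b = [None] * len(self.intercepts_)
        delta = (probs - Y) / n  # softmax + cross-entropy
        acts = [X, *hidden]
        for layer in range(len(self.coefs_) - 1, -1, -1):
            grads_W[layer] = acts[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.coefs_[layer].T
                if masks is not None and layer - 1 < len(masks) and masks[layer - 1] is not None:
                    delta = delta * masks[layer - 1]
                delta = delta * (hidden[layer - 1] > 0)
        for layer in range(len(self.coefs_)):
            grads_W[layer] = (
                grads_W[layer]
                + self.l1 * np.sign(self.coefs_[layer])
                + 2.0 * self.l2 * self.coefs_[layer]
            )
            grads_b[layer] = (
                grads_b[layer]
                + self.l1 * np.sign(self.intercepts_[layer])
                + 2.0 * self.l2 * self.intercepts_[layer]
            )
        return loss, grads_W, grads_b

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        Y = np.zeros((len(y), 2))
        Y[np.arange(len(y)), (y == classes[1]).astype(int)] = 1.0

        entropy = self._seed_entropy()
        self._init_params(X.shape[1], np.random.default_rng((entropy, 0xA11CE)))
        vel_W = [np.zeros_like(W) for W in self.coefs_]
        vel_b = [np.zeros_like(b) for b in self.intercepts_]
        dropout = tuple(self.dropout_rates)
        n = len(X)
        history = []
        for epoch in range(self.epochs):
            rng = np.random.default_rng((entropy, epoch))
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                masks = None
                if any(r > 0 for r in dropout):
                    masks = []
                    for layer, rate in enumerate(dropout):
                        if rate > 0:
                            keep = rng.random((len(idx), self.hidden_sizes[layer])) >= rate
                            masks.append(keep / (1.0 - rate))
                        else:
                            masks.append(None)
                loss, gW, gb = self.loss_and_gradients(X[idx], Y[idx], masks)
                batch_losses.append(loss)
                for layer in range(len(self.coefs_)):
                    vel_W[layer] = (
                        self.momentum * vel_W[layer] - self.learning_rate * gW[layer]
                    )
                    vel_b[layer] = (
                        self.momentum * vel_b[layer] - self.learning_rate * gb[layer]
                    )
                    self.coefs_[layer] = self.coefs_[layer] + vel_W[layer]
                    self.intercepts_[layer] = self.intercepts_[layer] + vel_b[layer]
            epoch_loss = float(np.mean(batch_losses))
            if not np.isfinite(epoch_loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            history.append(epoch_loss)
        self.loss_curve_ = history
        return self

    def _check_fitted(self):
        if not hasattr(self, "coefs_"):
            raise NotFittedError("classifier is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        """Inference-mode class probabilities (no dropout, no rescaling)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected shape (n, {self.n_features_in_}), got {X.shape}"
            )
        _, probs = self._forward(X)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive (second) class per example."""
        return self.predict_proba(X)[:, 1]

    def hidden_activations(self, X, layer: int) -> np.ndarray:
        """Inference-mode post-ReLU activations of hidden layer ``layer`` (1-based)."""
        self._check_fitted()
        if not (1 <= layer <= len(self.hidden_sizes)):
            raise ValueError(
                f"layer must be in 1..{len(self.hidden_sizes)}, got {layer}"
            )
        X = np.asarray(X, dtype=float)
        hidden, _ = self._forward(X)
        return hidden[layer - 1]

    # -- serialization helpers ----------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "n_features_in": int(self.n_features_in_),
            "coefs": [W.tolist() for W in self.coefs_],
            "intercepts": [b.tolist() for b in self.intercepts_],
            "loss_curve": list(getattr(self, "loss_curve_", [])),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DenseNetworkClassifier":
        params = dict(payload["params"])
        for key in ("hidden_sizes", "dropout_rates"):
            params[key] = tuple(params[key])
        clf = cls(**params)
        clf.classes_ = np.array(payload["classes"])
        clf.n_features_in_ = int(payload["n_features_in"])
        clf.coefs_ = [np.array(W, dtype=float) for W in payload["coefs"]]
        clf.intercepts_ = [np.array(b, dtype=float) for b in payload["intercepts"]]
        clf.loss_curve_ = list(payload["loss_curve"])
        return clf


def train(config: NetworkConfig, X, y) -> DenseNetworkClassifier:
    """Train the eight-layer site classifier from a config (thin wrapper)."""
    return config.classifier().fit(X, y)


def predict_proba(model: DenseNetworkClassifier, X) -> np.ndarray:
    """Positive-class probability per example (thin wrapper)."""
    return model.decision_scores(X)
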
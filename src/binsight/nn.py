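"""A compact feed-forward binary classifier in numpy.

Supports the four modern activations (ReLU, ELU, GELU, Swish), inverted
dropout on every hidden layer, a sigmoid output trained with binary
cross-entropy, and the Adadelta optimizer (rho = 0.95, eps = 1e-6) — a
scale-free update rule that tolerates its conventional learning rate of 1.
Training runs a fixed number of epochs with mini-batches; everything is
driven by a single seeded generator so fits are exactly repeatable.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["MLPBinaryClassifier", "ACTIVATIONS"]

_SQRT2 = np.sqrt(2.0)


def _relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z):
    return (z > 0).astype(z.dtype)


def _elu(z, alpha=1.0):
    return np.where(z > 0, z, alpha * np.expm1(z))


def _elu_grad(z, alpha=1.0):
    return np.where(z > 0, 1.0, alpha * np.exp(np.minimum(z, 0.0)))


def _gelu(z):
    return 0.5 * z * (1.0 + erf(z / _SQRT2))


def _gelu_grad(z):
    cdf = 0.5 * (1.0 + erf(z / _SQRT2))
    pdf = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    return cdf + z * pdf


def _swish(z):
    return z * expit(z)


def _swish_grad(z):
    s = expit(z)
    return s + z * s * (1.0 - s)


ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "elu": (_elu, _elu_grad),
    "gelu": (_gelu, _gelu_grad),
    "swish": (_swish, _swish_grad),
}


class _Adadelta:
    """Per-parameter Adadelta state: running averages of g^2 and dx^2."""

    def __init__(self, shapes, lr=1.0, rho=0.95, eps=1e-6):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.eg = [np.zeros(s) for s in shapes]
        self.edx = [np.zeros(s) for s in shapes]

    def step(self, params, grads):
        for p, g, eg, edx in zip(params, grads, self.eg, self.edx):
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt(edx + self.eps) / np.sqrt(eg + self.eps) * g
            edx *= self.rho
            edx += (1 - self.rho) * dx * dx
            p += self.lr * dx


class MLPBinaryClassifier(ClassifierMixin, BaseEstimator):
    """Multilayer perceptron for 0/1 classification.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Nodes per hidden layer; length is the number of hidden layers.
    dropout : float in [0, 1)
        Inverted-dropout rate applied to every hidden layer during training.
    activation : {"relu", "elu", "gelu", "swish"}
    learning_rate : float, default 1.0
        Adadelta step scale (1.0 is the conventional setting).
    epochs, batch_size : training schedule (fixed; no early stopping).
    random_state : seed for init, shuffling and dropout masks.
    """

    def __init__(self, hidden_layer_sizes=(16,), dropout=0.2,
                 activation="relu", learning_rate=1.0, epochs=100,
                 batch_size=32, random_state=None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.activation = activation
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(ACTIVATIONS)}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.classes_ = np.unique(y)
        if len(self.classes_) == 1:
            self._constant_ = float(self.classes_[0])
            return self
        if not set(self.classes_.tolist()) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        self._constant_ = None
        rng = np.random.default_rng(self.random_state)
        sizes = [X.shape[1], *map(int, np.atleast_1d(self.hidden_layer_sizes)), 1]
        self.coefs_, self.intercepts_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.coefs_.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
            self.intercepts_.append(np.zeros(fan_out))
        params = self.coefs_ + self.intercepts_
        opt = _Adadelta([p.shape for p in params], lr=self.learning_rate)
        yv = y.astype(float)[:, None]
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                grads = self._batch_grads(X[idx], yv[idx], rng)
                opt.step(params, grads)
        return self

    def _batch_grads(self, Xb, yb, rng):
        act, act_grad = ACTIVATIONS[self.activation]
        keep = 1.0 - self.dropout
        zs, activations, masks = [], [Xb], []
        h = Xb
        n_hidden = len(self.coefs_) - 1
        for layer, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = h @ W + b
            zs.append(z)
            if layer < n_hidden:
                a = act(z)
                if self.dropout > 0:
                    m = (rng.random(a.shape) < keep) / keep
                    a = a * m
                    masks.append(m)
                else:
                    masks.append(None)
                activations.append(a)
                h = a
            else:
                h = expit(z)  # sigmoid output
        m = Xb.shape[0]
        delta = (h - yb) / m  # dBCE/dz at the output
        gW = [None] * len(self.coefs_)
        gb = [None] * len(self.intercepts_)
        for layer in range(len(self.coefs_) - 1, -1, -1):
            gW[layer] = activations[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.coefs_[layer].T
                if masks[layer - 1] is not None:
                    delta = delta * masks[layer - 1]
                delta = delta * act_grad(zs[layer - 1])
        return gW + gb

    def _forward(self, X):
        act, _ = ACTIVATIONS[self.activation]
        h = X
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            h = act(h @ W + b)
        return expit(h @ self.coefs_[-1] + self.intercepts_[-1]).ravel()

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X, dtype=float)
        if self._constant_ is not None:
            p = np.full(X.shape[0], self._constant_)
        else:
            p = self._forward(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]
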
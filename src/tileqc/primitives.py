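"""Verified neural building blocks: the perceptron with its delta-rule
update, and 2-D image cross-correlation.

These are the primitives the rest of the stack is built from.  The
perceptron maps an input vector to {0, 1} via a hard threshold on
``w·x + b`` (strictly greater than zero activates); learning adjusts each
weight by ``α (d − y) x_i`` after every sample, with the bias trained as a
weight on a constant input of 1.  Cross-correlation slides a K×L kernel
over an M×N image and records the overlap sum ``C(i,j) = Σ_x Σ_y
w(x,y) f(x+i, y+j)``; in "valid" mode the output extent is
(M−K+1)×(N−L+1), in "same" mode the image is zero-padded so the output
matches the input extent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import InvalidArgumentError

__all__ = [
    "Perceptron",
    "TrainingSample",
    "perceptron_predict",
    "perceptron_update",
    "train_perceptron",
    "cross_correlate",
    "PerceptronClassifier",
]


@dataclass(frozen=True)
class Perceptron:
    """Immutable perceptron state: weights, bias, learning rate α."""

    weights: np.ndarray
    bias: float = 0.0
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if w.ndim != 1 or w.size < 1:
            raise InvalidArgumentError("weights must be a nonempty vector")
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning rate must be positive")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class TrainingSample:
    """One labeled input: vector x and binary target d."""

    x: np.ndarray
    d: int

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        if self.d not in (0, 1):
            raise InvalidArgumentError("target d must be 0 or 1")
        object.__setattr__(self, "x", x)


def _check_dim(p: Perceptron, x: np.ndarray) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != p.weights.shape:
        raise InvalidArgumentError(
            f"input dimension {x.shape} does not match weights {p.weights.shape}")
    return x


def perceptron_predict(p: Perceptron, x) -> int:
    """Hard-threshold activation: 1 iff w·x + b > 0 (strict), else 0."""
    x = _check_dim(p, x)
    return int(np.dot(p.weights, x) + p.bias > 0)


def perceptron_update(p: Perceptron, sample: TrainingSample) -> Perceptron:
    """One delta-rule step: w ← w + α(d − y)x, bias as weight on input 1.

    A correct prediction (d = y) leaves the state unchanged.
    """
    x = _check_dim(p, sample.x)
    y = perceptron_predict(p, x)
    err = sample.d - y
    if err == 0:
        return p
    return replace(p, weights=p.weights + p.learning_rate * err * x,
                   bias=p.bias + p.learning_rate * err)


def train_perceptron(
    p: Perceptron, samples: list[TrainingSample], max_epochs: int = 100
) -> tuple[Perceptron, int]:
    """Run delta-rule epochs until zero training error or max_epochs.

    Returns the trained perceptron and the number of epochs used.
    Converges for linearly separable data (perceptron convergence theorem).
    """
    for epoch in range(1, max_epochs + 1):
        mistakes = 0
        for s in samples:
            before = p
            p = perceptron_update(p, s)
            if p is not before:
                mistakes += 1
        if mistakes == 0:
            return p, epoch
    return p, max_epochs


def cross_correlate(image, kernel, mode: str = "valid") -> np.ndarray:
    """2-D cross-correlation of a kernel over an image.

    C(i,j) = Σ_x Σ_y w(x,y) · f(x+i, y+j), x over [0,K), y over [0,L).
    """
    f = np.asarray(image, dtype=float)
    w = np.asarray(kernel, dtype=float)
    if f.ndim != 2 or w.ndim != 2:
        raise InvalidArgumentError("image and kernel must be 2-D")
    m, n = f.shape
    k, l = w.shape
    if mode not in ("valid", "same"):
        raise InvalidArgumentError("mode must be 'valid' or 'same'")
    if mode == "valid" and (k > m or l > n):
        raise InvalidArgumentError(
            f"kernel {k}x{l} larger than image {m}x{n} in valid mode")
    if mode == "same":
        pt, pl = (k - 1) // 2, (l - 1) // 2
        f = np.pad(f, ((pt, k - 1 - pt), (pl, l - 1 - pl)))
        m, n = f.shape
    windows = np.lib.stride_tricks.sliding_window_view(f, (k, l))
    return np.einsum("ijkl,kl->ij", windows, w)


class PerceptronClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style front end for the delta-rule perceptron."""

    def __init__(self, learning_rate: float = 0.1, max_epochs: int = 100):
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs

    def fit(self, X, y) -> "PerceptronClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InvalidArgumentError("X must be 2-D with one row per label")
        samples = [TrainingSample(x=row, d=int(t)) for row, t in zip(X, y)]
        p = Perceptron(weights=np.zeros(X.shape[1]),
                       learning_rate=self.learning_rate)
        self.perceptron_, self.n_epochs_ = train_perceptron(
            p, samples, self.max_epochs)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([perceptron_predict(self.perceptron_, row) for row in X])
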
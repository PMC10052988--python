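"""Binary good/poor tile classifier and its training protocol.

The protocol mirrors the quality-filtering stage of the histology pipeline:
a stratified split holds out 40% of the labeled tiles for testing; the
network — a small conv-pool stack whose filter width doubles per block —
is trained with Adam at learning rate 0.001 under on-the-fly flip /
rotation / shift augmentation, with per-epoch accuracy and loss recorded
on a stratified 10% validation slice of the training set.  Evaluation
reports the TP/TN/FP/FN confusion counts, and ``detect_overfitting``
flags the epoch at which validation loss stops improving while training
loss keeps falling (the classic divergence of the two curves).

Splits, batch order, augmentation draws and weight initialization are all
driven by the config seed; bitwise weight-level reproducibility across
platforms is best-effort (floating-point reduction order may differ), while
sample ordering is strictly deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from . import nnet
from .exceptions import InvalidArgumentError
from .synthetic import LabeledTile

__all__ = [
    "AugmentConfig",
    "CNNConfig",
    "SplitSpec",
    "TrainRun",
    "split_dataset",
    "train_quality_cnn",
    "evaluate",
    "detect_overfitting",
    "QualityCNN",
]

LABELS = ("poor", "good")  # class 0, class 1


@dataclass(frozen=True)
class AugmentConfig:
    """On-the-fly training-stream augmentation."""

    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_max: float = 15.0      # degrees
    shift_max: float = 0.05         # fraction of the tile extent

    def __post_init__(self) -> None:
        if not 0 <= self.rotation_max <= 180:
            raise InvalidArgumentError("rotation_max must be in [0, 180] degrees")
        if not 0 <= self.shift_max < 0.5:
            raise InvalidArgumentError("shift_max must be in [0, 0.5)")


@dataclass(frozen=True)
class CNNConfig:
    """Network and training hyper-parameters."""

    input_size: int = 256
    conv_blocks: int = 3
    base_filters: int = 16          # doubles per block: 16, 32, 64, ...
    dense_units: int = 64
    dropout_rates: tuple[float, float] = (0.25, 0.5)
    learning_rate: float = 0.001    # Adam
    epochs: int = 50
    batch_size: int = 32
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be positive")
        if self.conv_blocks < 1:
            raise InvalidArgumentError("need at least one conv block")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split: 40% held out for testing by default."""

    test_fraction: float = 0.40
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise InvalidArgumentError("test_fraction must be in (0, 1)")


@dataclass
class TrainRun:
    """Per-epoch learning curves plus final test metrics."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    test_accuracy: float | None = None
    confusion: dict[str, int] | None = None


def _as_xy(tiles, input_size: int | None = None):
    """LabeledTiles (or (image, label) pairs) -> float images in [0,1] + 0/1 labels."""
    images, labels = [], []
    for t in tiles:
        if isinstance(t, LabeledTile):
            img, lab = t.image, t.quality_label
        else:
            img, lab = t
        img = np.asarray(img, dtype=float) / 255.0
        if input_size is not None and img.shape[0] != input_size:
            zoom = input_size / img.shape[0]
            img = ndimage.zoom(img, (zoom, input_size / img.shape[1], 1), order=1)
        images.append(img)
        labels.append(LABELS.index(lab) if isinstance(lab, str) else int(lab))
    return np.stack(images), np.asarray(labels)


def split_dataset(tiles, spec: SplitSpec | None = None):
    """Deterministic stratified split into (train, test) tile lists."""
    spec = spec or SplitSpec()
    tiles = list(tiles)
    labels = [t.quality_label if isinstance(t, LabeledTile) else t[1] for t in tiles]
    counts = {lab: labels.count(lab) for lab in set(labels)}
    if any(c < 2 for c in counts.values()):
        raise InvalidArgumentError(
            f"every class needs at least 2 members for a stratified split, got {counts}")
    idx = np.arange(len(tiles))
    train_idx, test_idx = train_test_split(
        idx, test_size=spec.test_fraction, random_state=spec.seed,
        stratify=labels if spec.stratified else None)
    return [tiles[i] for i in sorted(train_idx)], [tiles[i] for i in sorted(test_idx)]


def _augment(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.horizontal_flip and rng.random() < 0.5:
        img = img[:, ::-1]
    if cfg.vertical_flip and rng.random() < 0.5:
        img = img[::-1]
    if cfg.rotation_max > 0:
        angle = rng.uniform(-cfg.rotation_max, cfg.rotation_max)
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                             order=1, mode="nearest")
    if cfg.shift_max > 0:
        h, w = img.shape[:2]
        dy = rng.uniform(-cfg.shift_max, cfg.shift_max) * h
        dx = rng.uniform(-cfg.shift_max, cfg.shift_max) * w
        img = ndimage.shift(img, (dy, dx, 0), order=1, mode="nearest")
    return np.ascontiguousarray(img)


def _build_network(cfg: CNNConfig, rng: np.random.Generator) -> nnet.Sequential:
    layers: list[nnet.Layer] = []
    size, channels = cfg.input_size, 3
    for b in range(cfg.conv_blocks):
        filters = cfg.base_filters * (2 ** b)
        layers += [nnet.Conv2D(channels, filters, 3, rng), nnet.ReLU(),
                   nnet.MaxPool2x2()]
        size = (size - 2) // 2
        channels = filters
        if size < 2:
            raise InvalidArgumentError(
                f"input_size {cfg.input_size} too small for {cfg.conv_blocks} conv blocks")
    layers.append(nnet.Flatten())
    feat = size * size * channels
    layers += [nnet.Dropout(cfg.dropout_rates[0], rng),
               nnet.Dense(feat, cfg.dense_units, rng), nnet.ReLU(),
               nnet.Dropout(cfg.dropout_rates[1], rng),
               nnet.Dense(cfg.dense_units, 1, rng)]
    return nnet.Sequential(layers)


def train_quality_cnn(train_tiles, config: CNNConfig | None = None):
    """Train the binary quality classifier; returns (model, TrainRun).

    A stratified ``validation_fraction`` slice of the training tiles is
    held out for the per-epoch curves; augmentation touches only the
    training stream.
    """
    config = config or CNNConfig()
    x, y = _as_xy(train_tiles, config.input_size)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("training set must contain both classes")

    idx = np.arange(len(y))
    tr_idx, val_idx = train_test_split(
        idx, test_size=config.validation_fraction,
        random_state=config.seed, stratify=y)
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    rng = np.random.default_rng(config.seed)
    net = _build_network(config, rng)
    opt = nnet.Adam(net.params, learning_rate=config.learning_rate)
    run = TrainRun()

    for _epoch in range(config.epochs):
        order = rng.permutation(len(y_tr))
        losses, hits, total = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            xb = np.stack([_augment(x_tr[i], config.augmentation, rng)
                           for i in batch])
            yb = y_tr[batch].astype(float)
            p = net.forward(xb, training=True)
            losses.append(nnet.bce_loss(p, yb))
            hits += int(((p >= 0.5).astype(int) == yb).sum())
            total += len(batch)
            net.backward(p, yb)
            opt.step()
        run.train_loss.append(float(np.mean(losses)))
        run.train_accuracy.append(hits / total)

        p_val = net.forward(x_val, training=False)
        run.val_loss.append(nnet.bce_loss(p_val, y_val.astype(float)))
        run.val_accuracy.append(float(((p_val >= 0.5).astype(int) == y_val).mean()))
    return net, run


def evaluate(model: nnet.Sequential, test_tiles, input_size: int | None = None):
    """Confusion counts and accuracy on a test set.

    Positive class is 'good'.  Returns a dict with TP, TN, FP, FN and
    accuracy; the four counts partition the test set.
    """
    test_tiles = list(test_tiles)
    if not test_tiles:
        raise InvalidArgumentError("test set must be nonempty")
    x, y = _as_xy(test_tiles, input_size)
    pred = (model.forward(x, training=False) >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "accuracy": (tp + tn) / len(y)}


def detect_overfitting(run: TrainRun, patience: int = 5) -> int | None:
    """First epoch (1-based) where validation loss has not improved for
    ``patience`` epochs while training loss is still declining; None if
    the curves never diverge that way."""
    if patience < 1:
        raise InvalidArgumentError("patience must be >= 1")
    val, train = run.val_loss, run.train_loss
    best, best_epoch = np.inf, 0
    for e in range(1, len(val) + 1):
        if val[e - 1] < best - 1e-12:
            best, best_epoch = val[e - 1], e
        elif e - best_epoch >= patience and train[e - 1] < train[best_epoch - 1]:
            return e
    return None


class QualityCNN(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style binary tile-quality classifier.

    ``fit(X, y)`` accepts an N×H×W×3 uint8 array (or a list of LabeledTile)
    with 0/1 or 'poor'/'good' labels; ``predict`` returns 0/1.

    Attributes
    ----------
    model_ : the trained network
    history_ : TrainRun with per-epoch curves
    classes_ : array([0, 1])
    """

    def __init__(self, input_size: int = 64, conv_blocks: int = 2,
                 base_filters: int = 16, dense_units: int = 64,
                 dropout_rates: tuple[float, float] = (0.25, 0.5),
                 learning_rate: float = 0.001, epochs: int = 10,
                 batch_size: int = 8, augment: bool = True, seed: int = 0):
        self.input_size = input_size
        self.conv_blocks = conv_blocks
        self.base_filters = base_filters
        self.dense_units = dense_units
        self.dropout_rates = dropout_rates
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.augment = augment
        self.seed = seed

    def _config(self) -> CNNConfig:
        aug = AugmentConfig() if self.augment else AugmentConfig(
            horizontal_flip=False, vertical_flip=False,
            rotation_max=0.0, shift_max=0.0)
        return CNNConfig(input_size=self.input_size, conv_blocks=self.conv_blocks,
                         base_filters=self.base_filters, dense_units=self.dense_units,
                         dropout_rates=tuple(self.dropout_rates),
                         learning_rate=self.learning_rate, epochs=self.epochs,
                         batch_size=self.batch_size, augmentation=aug,
                         seed=self.seed)

    def fit(self, X, y=None) -> "QualityCNN":
        tiles = X if y is None else list(zip(np.asarray(X), y))
        self.model_, self.history_ = train_quality_cnn(tiles, self._config())
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        x, _ = _as_xy([(np.asarray(img), 0) for img in X], self.input_size)
        p = self.model_.forward(x, training=False)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
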
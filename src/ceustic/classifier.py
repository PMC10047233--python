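"""Five-class lesion classifier over clinical + TIC features.

A deliberately small feed-forward network — a dense layer of 8 units over
the 8 input features, two hidden layers of 6 units, and a 5-unit softmax
output (203 trainable parameters in total) — trained with focal
cross-entropy

    FCE = -sum_i alpha * (1 - p_i)**gamma * t_i * log(p_i)

(alpha = 0.25, gamma = 2.0; gamma = 0, alpha = 1 recovers plain
cross-entropy), RMSProp at learning rate 1e-4, 100 epochs, batch size 50.
Class imbalance is handled by duplicating random minority-class training
rows until all classes match the majority count; the stratified 70/30
train/validation split happens *before* oversampling so no validation row
leaks into training.  Features are z-scored using training-split
statistics, since the raw scales (age in years vs. AUC in
intensity-seconds) differ by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .synthetic import FEATURE_COLUMNS, LABEL_COLUMNS

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "FeedForwardClassifier",
    "TrainedModel",
    "count_parameters",
    "focal_cross_entropy",
    "oversample",
    "split_dataset",
    "train_classifier",
    "predict",
    "probability_report",
    "dataset_from_frame",
    "save_model",
    "load_model",
]

_LOG_EPS = 1e-7


@dataclass(frozen=True)
class NetworkSpec:
    """Dense layer widths over the 8-feature input; softmax output."""

    n_features: int = 8
    layer_widths: tuple[int, ...] = (8, 6, 6, 5)

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 1:
            raise ValueError("need at least one layer")

    @property
    def n_classes(self) -> int:
        return self.layer_widths[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol of the classifier."""

    alpha: float = 0.25
    gamma: float = 2.0
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 50
    split_fraction: float = 0.70
    seed: int = 0
    rms_rho: float = 0.9
    rms_eps: float = 1e-7

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split fraction must be in (0, 1)")


def count_parameters(spec: NetworkSpec) -> int:
    """Number of trainable parameters: sum over layers of in*out + out."""
    total = 0
    n_in = spec.n_features
    for width in spec.layer_widths:
        total += n_in * width + width
        n_in = width
    return total


def focal_cross_entropy(
    probabilities: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.25,
    gamma: float = 2.0,
) -> float:
    """Focal cross-entropy of softmax probabilities against one-hot labels.

    Accepts a single probability vector + one-hot label, or batches of
    either (the batch mean is returned).  True-class probabilities are
    clipped at 1e-7 before the log.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    t = np.atleast_2d(np.asarray(labels, dtype=float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probabilities must be non-negative and sum to 1")
    if not np.all((t == 0) | (t == 1)) or np.any(t.sum(axis=1) != 1):
        raise ValueError("labels must be one-hot")
    pt = np.clip((p * t).sum(axis=1), _LOG_EPS, 1.0)
    losses = -alpha * (1.0 - pt) ** gamma * np.log(pt)
    return float(losses.mean())


class FeedForwardClassifier:
    """The dense network; layers per :class:`NetworkSpec`, ReLU hidden, softmax out."""

    def __init__(self, spec: NetworkSpec = NetworkSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers: list[_nn.Dense] = []
        n_in = spec.n_features
        for i, width in enumerate(spec.layer_widths):
            last = i == len(spec.layer_widths) - 1
            self.layers.append(_nn.Dense(n_in, width, rng, relu=not last))
            n_in = width
        self.trained = False

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(x, dtype=float))
        for layer in self.layers:
            z = layer.forward(z)
        return _nn.softmax(z)

    def backward_from_focal(
        self, probs: np.ndarray, onehot: np.ndarray, alpha: float, gamma: float
    ) -> None:
        """Backpropagate the batch-mean focal loss through the softmax."""
        n = probs.shape[0]
        pt = np.clip((probs * onehot).sum(axis=1), _LOG_EPS, 1.0)
        # dL/dpt of  -alpha (1-pt)^gamma log pt
        if gamma == 0.0:
            dl_dpt = -alpha / pt
        else:
            dl_dpt = -alpha * (
                -gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt)
                + (1.0 - pt) ** gamma / pt
            )
        # dpt/dz_j = pt * (1[j = true] - p_j)  (softmax Jacobian row)
        dz = dl_dpt[:, None] * pt[:, None] * (onehot - probs) / n
        d = dz
        for layer in reversed(self.layers):
            d = layer.backward(d)


@dataclass
class TrainedModel:
    """A trained classifier plus the standardisation learned on the training split."""

    network: FeedForwardClassifier
    mean: np.ndarray
    std: np.ndarray
    config: TrainConfig
    history: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(np.asarray(features, dtype=float)) - self.mean) / self.std
        return self.network.forward(x)


def oversample(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate random minority-class rows until all class counts match the majority.

    Original rows are all retained; added rows are exact copies drawn
    uniformly with replacement.  Deterministic given the seed.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts == 0):
        raise ValueError("every class must have at least one sample")
    target = counts.max()
    rng = np.random.default_rng(seed)
    extra_idx = []
    for cls, count in zip(classes, counts):
        if count < target:
            members = np.flatnonzero(y == cls)
            extra_idx.append(rng.choice(members, size=target - count, replace=True))
    if not extra_idx:
        return X.copy(), y.copy()
    idx = np.concatenate([np.arange(len(y))] + extra_idx)
    return X[idx], y[idx]


def split_dataset(
    X: np.ndarray, y: np.ndarray, fraction: float = 0.70, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation split: ceil(fraction * n_c) of each class trains."""
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        if len(members) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples; cannot split")
        k = int(np.ceil(fraction * len(members)))
        k = min(k, len(members) - 1)  # keep at least one validation sample
        train_idx.append(members[:k])
        val_idx.append(members[k:])
    tr = np.concatenate(train_idx)
    va = np.concatenate(val_idx)
    return X[tr], y[tr], X[va], y[va]


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    spec: NetworkSpec = NetworkSpec(),
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Run the full training protocol and return the fitted model.

    Order of operations: stratified split -> z-score standardisation with
    training statistics -> oversampling of the training split only ->
    RMSProp/focal-loss training.  The returned history holds per-epoch
    train and validation loss and categorical accuracy.  Deterministic for
    a fixed config seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    X_tr, y_tr, X_va, y_va = split_dataset(X, y, config.split_fraction, config.seed)
    mean = X_tr.mean(axis=0)
    std = X_tr.std(axis=0)
    std[std == 0] = 1.0
    X_tr = (X_tr - mean) / std
    X_va = (X_va - mean) / std
    X_tr, y_tr = oversample(X_tr, y_tr, seed=config.seed)

    net = FeedForwardClassifier(spec, seed=config.seed)
    opt = _nn.RMSProp(net.params, lr=config.learning_rate,
                      rho=config.rms_rho, eps=config.rms_eps)
    rng = np.random.default_rng(config.seed)
    t_tr = _one_hot(y_tr, spec.n_classes)
    t_va = _one_hot(y_va, spec.n_classes)
    history: dict[str, list[float]] = {
        "train_loss": [], "val_loss": [], "train_accuracy": [], "val_accuracy": [],
    }

    for epoch in range(config.epochs):
        perm = rng.permutation(len(y_tr))
        for start in range(0, len(y_tr), config.batch_size):
            idx = perm[start:start + config.batch_size]
            probs = net.forward(X_tr[idx])
            net.backward_from_focal(probs, t_tr[idx], config.alpha, config.gamma)
            opt.step(net.grads)

        p_tr = net.forward(X_tr)
        p_va = net.forward(X_va)
        train_loss = focal_cross_entropy(p_tr, t_tr, config.alpha, config.gamma)
        val_loss = focal_cross_entropy(p_va, t_va, config.alpha, config.gamma)
        if not np.isfinite(train_loss):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["train_accuracy"].append(float((p_tr.argmax(1) == y_tr).mean()))
        history["val_accuracy"].append(float((p_va.argmax(1) == y_va).mean()))

    net.trained = True
    return TrainedModel(net, mean, std, config, history)


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Class probabilities (ordered per ``LABEL_COLUMNS``) for one feature vector."""
    if not model.network.trained:
        raise RuntimeError("model has not been trained")
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    probs = model.predict_proba(features)
    return probs[0] if features.ndim == 1 else probs


def probability_report(probs: np.ndarray) -> dict[str, float]:
    """Per-class probability report keyed by lesion class name."""
    return {name: float(p) for name, p in zip(LABEL_COLUMNS, probs)}


def dataset_from_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, y): the 8 features and integer labels."""
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = df.loc[:, list(FEATURE_COLUMNS)].to_numpy(float)
    labels = df.loc[:, list(LABEL_COLUMNS)].to_numpy(int)
    if not np.all(labels.sum(axis=1) == 1):
        raise ValueError("label columns must be one-hot")
    return X, labels.argmax(axis=1)


def save_model(model: TrainedModel, path: str | Path) -> None:
    arrays = {f"p{i}": p for i, p in enumerate(model.network.params)}
    np.savez(
        Path(path),
        _widths=np.array(model.network.spec.layer_widths, dtype=np.int64),
        _n_features=np.array([model.network.spec.n_features], dtype=np.int64),
        _mean=model.mean,
        _std=model.std,
        **arrays,
    )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path)) as data:
        spec = NetworkSpec(int(data["_n_features"][0]), tuple(int(w) for w in data["_widths"]))
        net = FeedForwardClassifier(spec)
        for i, p in enumerate(net.params):
            p[...] = data[f"p{i}"]
        net.trained = True
        return TrainedModel(net, data["_mean"].copy(), data["_std"].copy(), TrainConfig())
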
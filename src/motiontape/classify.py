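"""Movement classifiers: CNN-LSTM, transformer encoder, and boosted trees.

The deep heads consume the raw channel-by-time feature tensor; the
boosted-tree head consumes per-channel summary statistics (config-switchable
to full flattening).  All training is seeded and deterministic.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from .features import FeatureTensor
from .nn import (
    LSTM,
    Adam,
    Conv1d,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    log_softmax,
    sinusoidal_positions,
    softmax,
)
from .simdata import MOVEMENTS

__all__ = [
    "ClassifierConfig",
    "ClassifierModel",
    "train_classifier",
    "predict",
    "predict_batch",
    "score",
]

KINDS = ("cnn_lstm", "transformer", "gbt")


@dataclass(frozen=True)
class ClassifierConfig:
    kind: str = "cnn_lstm"
    # CNN-LSTM head
    lstm_hidden: int = 100
    lstm_layers: int = 2
    conv_channels: tuple[int, int] = (32, 64)
    conv_kernel: int = 5
    conv_stride: int = 2
    # transformer head
    encoder_layers: int = 4
    latent_dim: int = 12
    # boosted-tree head
    gbt_learning_rate: float = 0.01
    gbt_max_depth: int = 3
    gbt_n_estimators: int = 300
    gbt_flatten: bool = False
    # shared training budget
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind: {self.kind!r}")
        if min(self.lstm_hidden, self.lstm_layers, self.encoder_layers, self.latent_dim) < 1:
            raise ValueError("architecture counts must be >= 1")
        if self.gbt_learning_rate <= 0 or self.learning_rate <= 0:
            raise ValueError("learning rates must be positive")

    def with_(self, **kwargs) -> "ClassifierConfig":
        return replace(self, **kwargs)


class CNNLSTMNet(Module):
    def __init__(self, n_channels: int, n_classes: int, config: ClassifierConfig, rng):
        c1, c2 = config.conv_channels
        self.conv1 = Conv1d(n_channels, c1, config.conv_kernel, config.conv_stride, rng)
        self.conv2 = Conv1d(c1, c2, config.conv_kernel, config.conv_stride, rng)
        self.lstm = LSTM(c2, config.lstm_hidden, config.lstm_layers, rng)
        self.head = Linear(config.lstm_hidden, n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, C, T) -> logits (B, n_classes)
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        seq = self.lstm(h.transpose(0, 2, 1))
        return self.head(seq[:, -1, :])


class TransformerClassifierNet(Module):
    def __init__(self, n_channels: int, n_classes: int, config: ClassifierConfig, rng):
        d = config.latent_dim
        self.embed = Linear(n_channels, d, rng)
        self.blocks = [
            TransformerEncoderLayer(d, 2 * d, rng) for _ in range(config.encoder_layers)
        ]
        self.head = Linear(d, n_classes, rng)
        self.d = d

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, C, T)
        h = self.embed(x.transpose(0, 2, 1))
        h = h + Tensor(sinusoidal_positions(h.shape[1], self.d))
        for block in self.blocks:
            h = block(h)
        return self.head(h.mean(axis=1))


@dataclass
class ClassifierModel:
    kind: str
    config: ClassifierConfig
    labels: tuple[str, ...]
    n_channels: int
    n_steps: int
    net: object  # Module for deep heads, fitted sklearn estimator for gbt
    seed: int = 0
    loss_history: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _stable_labels(values: list[str]) -> tuple[str, ...]:
    present = set(values)
    canonical = [m for m in MOVEMENTS if m in present]
    if len(canonical) == len(present):
        return tuple(canonical)
    return tuple(sorted(present))


def summary_features(x: np.ndarray) -> np.ndarray:
    """Per-channel summary statistics for the tree head: (N, 8*C)."""
    mean = x.mean(axis=2)
    sd = x.std(axis=2)
    lo = x.min(axis=2)
    hi = x.max(axis=2)
    med = np.median(x, axis=2)
    iqr = np.percentile(x, 75, axis=2) - np.percentile(x, 25, axis=2)
    argmax_t = x.argmax(axis=2) / max(x.shape[2] - 1, 1)
    spectrum = np.abs(np.fft.rfft(x, axis=2))
    dom_freq = spectrum[:, :, 1:].argmax(axis=2) / max(spectrum.shape[2] - 1, 1)
    return np.concatenate([mean, sd, lo, hi, med, iqr, argmax_t, dom_freq], axis=1)


def _check_homogeneous(dataset: list[FeatureTensor]) -> tuple[int, int]:
    shapes = {t.values.shape for t in dataset}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous feature shapes: {sorted(shapes)}")
    return shapes.pop()


def train_classifier(
    dataset: list[FeatureTensor], config: ClassifierConfig = ClassifierConfig()
) -> ClassifierModel:
    """Fit the configured head on labeled feature tensors."""
    if not dataset:
        raise ValueError("empty training dataset")
    n_channels, n_steps = _check_homogeneous(dataset)
    labels = _stable_labels([t.label for t in dataset])
    if len(labels) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    x = np.stack([t.values for t in dataset])
    y = np.array([labels.index(t.label) for t in dataset])

    if config.kind == "gbt":
        feats = x.reshape(len(x), -1) if config.gbt_flatten else summary_features(x)
        est = GradientBoostingClassifier(
            learning_rate=config.gbt_learning_rate,
            max_depth=config.gbt_max_depth,
            n_estimators=config.gbt_n_estimators,
            random_state=config.seed,
        )
        est.fit(feats, y)
        return ClassifierModel(
            kind="gbt",
            config=config,
            labels=labels,
            n_channels=n_channels,
            n_steps=n_steps,
            net=est,
            seed=config.seed,
        )

    rng = np.random.default_rng(config.seed)
    if config.kind == "cnn_lstm":
        net = CNNLSTMNet(n_channels, len(labels), config, rng)
    else:
        net = TransformerClassifierNet(n_channels, len(labels), config, rng)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history: list[float] = []
    best, stale = np.inf, 0
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net(Tensor(x[idx]))
            logp = log_softmax(logits, axis=1)
            loss = -logp[np.arange(len(idx)), y[idx]].mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        epoch_loss /= n_batches
        history.append(epoch_loss)
        if epoch_loss < best - 1e-4:
            best, stale = epoch_loss, 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
    return ClassifierModel(
        kind=config.kind,
        config=config,
        labels=labels,
        n_channels=n_channels,
        n_steps=n_steps,
        net=net,
        seed=config.seed,
        loss_history=history,
    )


def _probabilities(model: ClassifierModel, x: np.ndarray) -> np.ndarray:
    if model.kind == "gbt":
        feats = (
            x.reshape(len(x), -1) if model.config.gbt_flatten else summary_features(x)
        )
        probs = np.zeros((len(x), len(model.labels)))
        probs[:, model.net.classes_.astype(int)] = model.net.predict_proba(feats)
        return probs
    logits = model.net(Tensor(x))
    return softmax(logits, axis=1).data


def predict_batch(
    model: ClassifierModel, samples: list[FeatureTensor]
) -> tuple[list[str], np.ndarray]:
    """Predicted labels and class-probability rows for a batch."""
    if not samples:
        return [], np.zeros((0, len(model.labels)))
    for s in samples:
        if s.values.shape != (model.n_channels, model.n_steps):
            raise ValueError(
                f"sample shape {s.values.shape} does not match model "
                f"({model.n_channels}, {model.n_steps})"
            )
    x = np.stack([s.values for s in samples])
    probs = _probabilities(model, x)
    labels = [model.labels[i] for i in probs.argmax(axis=1)]
    return labels, probs


def predict(model: ClassifierModel, sample: FeatureTensor) -> tuple[str, np.ndarray]:
    labels, probs = predict_batch(model, [sample])
    return labels[0], probs[0]


def score(model: ClassifierModel, testset: list[FeatureTensor]) -> dict:
    """Accuracy plus one-vs-rest precision/recall per class and macro rows."""
    if not testset:
        raise ValueError("empty test set")
    predicted, _ = predict_batch(model, testset)
    actual = [t.label for t in testset]
    correct = sum(p == a for p, a in zip(predicted, actual))
    per_class = {}
    for lab in model.labels:
        tp = sum(1 for p, a in zip(predicted, actual) if p == lab and a == lab)
        fp = sum(1 for p, a in zip(predicted, actual) if p == lab and a != lab)
        fn = sum(1 for p, a in zip(predicted, actual) if p != lab and a == lab)
        per_class[lab] = {
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
            "support": sum(1 for a in actual if a == lab),
        }
    return {
        "accuracy": correct / len(testset),
        "per_class": per_class,
        "macro_precision": float(np.mean([v["precision"] for v in per_class.values()])),
        "macro_recall": float(np.mean([v["recall"] for v in per_class.values()])),
        "n": len(testset),
    }
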
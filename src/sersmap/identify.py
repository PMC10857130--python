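"""5-layer 1D convolutional classifier for NMF feature spectra.

Architecture: 1D convolution → ReLU → fully-connected → ReLU →
fully-connected, with a softmax output over the three classes
{0 interference, 1 BZD, 2 EBZD}.  Training uses the Adam optimizer on
cross-entropy with a cosine-annealing learning-rate schedule (initial 1e-4,
minimum 1e-5, warm restarts every 10 epochs) and a stratified 7:3
train/validation split.  Each spectrum is normalized by its own maximum
before entering the network, so classification rests on spectral shape, not
absolute intensity.

The network is implemented directly in numpy: forward and backward passes,
Adam, and the schedule are all explicit, which keeps training bit-reproducible
under a seed and dependency-light.  The model is tiny (a few thousand
parameters) and trains on the ~100-spectrum datasets in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .scan import LabeledSpectrumDataset, DimensionalError

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "SpectrumClassifier",
    "build_classifier",
    "lr_schedule",
    "split_dataset",
    "train_classifier",
    "evaluate",
    "predict_component_labels",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the classifier and its training schedule."""

    input_length: int = 308
    conv_channels: int = 8
    kernel_size: int = 7
    stride: int = 1
    hidden_units: int = 64
    n_classes: int = 3
    lr_init: float = 1e-4
    lr_min: float = 1e-5
    cosine_period_epochs: int = 10
    epochs: int = 100
    batch_size: int = 8
    split_ratio: float = 0.7
    seed: int = 42

    def __post_init__(self) -> None:
        if self.lr_min >= self.lr_init:
            raise ValueError("lr_min must be below lr_init")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.n_classes != 3:
            raise ValueError("classifier is defined for 3 classes")
        if self.kernel_size > self.input_length:
            raise ValueError("kernel cannot exceed the input length")
        if self.stride < 1:
            raise ValueError("stride must be at least 1")


@dataclass
class ClassifierReport:
    """Loss curves and/or evaluation results of a classifier."""

    train_loss: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    confusion: np.ndarray | None = None  # rows = true class, cols = predicted
    accuracy: float | None = None


def lr_schedule(epoch: int, config: ClassifierConfig) -> float:
    """Cosine-annealing learning rate with warm restarts.

    η(t) = lr_min + (lr_init − lr_min)·(1 + cos(π·(t mod T)/T))/2 with
    T = cosine_period_epochs; the rate restarts at lr_init every period.
    """
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    T = config.cosine_period_epochs
    phase = (epoch % T) / T
    return config.lr_min + (config.lr_init - config.lr_min) * (
        1 + np.cos(np.pi * phase)
    ) / 2


def _normalize_spectra(X: np.ndarray) -> np.ndarray:
    """Divide each spectrum by its maximum (zero spectra pass through)."""
    mx = X.max(axis=1, keepdims=True)
    return np.where(mx > 0, X / np.where(mx > 0, mx, 1.0), X)


def _pad_to_length(X: np.ndarray, L: int) -> np.ndarray:
    """Right-pad short spectra with their last value to length L."""
    if X.shape[1] == L:
        return X
    if X.shape[1] > L:
        raise DimensionalError(f"spectra of length {X.shape[1]} exceed {L}")
    pad = np.repeat(X[:, -1:], L - X.shape[1], axis=1)
    return np.hstack([X, pad])


class SpectrumClassifier:
    """The 5-layer network with explicit numpy forward/backward passes."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        L, C, K = config.input_length, config.conv_channels, config.kernel_size
        self.conv_out_len = (L - K) // config.stride + 1
        flat = C * self.conv_out_len
        rng = np.random.default_rng(config.seed)
        # He-normal initialization, biases at zero
        self.params = {
            "Wc": rng.normal(0.0, np.sqrt(2.0 / K), (C, K)),
            "bc": np.zeros(C),
            "W1": rng.normal(0.0, np.sqrt(2.0 / flat), (flat, config.hidden_units)),
            "b1": np.zeros(config.hidden_units),
            "W2": rng.normal(
                0.0, np.sqrt(2.0 / config.hidden_units),
                (config.hidden_units, config.n_classes),
            ),
            "b2": np.zeros(config.n_classes),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        windows = sliding_window_view(X, cfg.kernel_size, axis=1)[:, :: cfg.stride]
        conv = np.einsum("blk,ck->bcl", windows, self.params["Wc"])
        conv += self.params["bc"][None, :, None]
        relu1 = np.maximum(conv, 0.0)
        flat = relu1.reshape(X.shape[0], -1)
        z1 = flat @ self.params["W1"] + self.params["b1"]
        relu2 = np.maximum(z1, 0.0)
        logits = relu2 @ self.params["W2"] + self.params["b2"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return {
            "windows": windows, "conv": conv, "flat": flat,
            "relu2": relu2, "probs": probs,
        }

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = _normalize_spectra(_pad_to_length(np.asarray(X, dtype=float),
                                              self.config.input_length))
        return self._forward(X)["probs"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class per spectrum; argmax breaks ties toward the lower class index.

        A spectrum with no signal at all (max ≤ 0) is interference by
        definition and is labeled 0 without consulting the network.
        """
        X = np.asarray(X, dtype=float)
        labels = np.argmax(self.predict_proba(X), axis=1)
        labels[X.max(axis=1) <= 0] = 0
        return labels

    # -- backward / optimization -------------------------------------------

    def _loss_and_grads(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        cfg = self.config
        B = X.shape[0]
        cache = self._forward(X)
        probs = cache["probs"]
        loss = float(-np.log(probs[np.arange(B), y] + 1e-12).mean())

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        grads = {}
        grads["W2"] = cache["relu2"].T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        drelu2 = dlogits @ self.params["W2"].T
        dz1 = drelu2 * (cache["relu2"] > 0)
        grads["W1"] = cache["flat"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ self.params["W1"].T
        dconv = dflat.reshape(B, cfg.conv_channels, self.conv_out_len)
        dconv = dconv * (cache["conv"] > 0)
        grads["Wc"] = np.einsum("bcl,blk->ck", dconv, cache["windows"])
        grads["bc"] = dconv.sum(axis=(0, 2))
        return loss, grads

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def mean_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self._forward(X)["probs"]
        return float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SpectrumClassifier":
        payload = json.loads(Path(path).read_text())
        model = cls(ClassifierConfig(**payload["config"]))
        for k, v in payload["params"].items():
            model.params[k] = np.asarray(v, dtype=float)
        return model


def build_classifier(config: ClassifierConfig | None = None) -> SpectrumClassifier:
    """Construct the conv → ReLU → FC → ReLU → FC (softmax) network."""
    return SpectrumClassifier(config or ClassifierConfig())


def split_dataset(
    dataset: LabeledSpectrumDataset,
    ratio: float = 0.7,
    seed: int = 42,
) -> tuple[LabeledSpectrumDataset, LabeledSpectrumDataset]:
    """Stratified shuffled train/validation split.

    Per label, round(ratio·n_label) samples go to the training side.  The two
    sides partition the dataset (disjoint, complete) and the split is
    deterministic per seed.  A label with fewer than 2 samples goes entirely
    to the training side with a warning.
    """
    import warnings

    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    valid_idx: list[int] = []
    for label in np.unique(dataset.labels):
        idx = np.nonzero(dataset.labels == label)[0]
        if idx.size < 2:
            warnings.warn(
                f"label {label} has {idx.size} sample(s); kept in training set",
                stacklevel=2,
            )
            train_idx.extend(idx.tolist())
            continue
        perm = rng.permutation(idx)
        n_train = int(round(ratio * idx.size))
        train_idx.extend(perm[:n_train].tolist())
        valid_idx.extend(perm[n_train:].tolist())
    return (
        dataset.subset(sorted(train_idx), "train"),
        dataset.subset(sorted(valid_idx), "valid"),
    )


def train_classifier(
    train: LabeledSpectrumDataset,
    valid: LabeledSpectrumDataset | None,
    config: ClassifierConfig | None = None,
) -> tuple[SpectrumClassifier, ClassifierReport]:
    """Train the network with Adam + cosine annealing; returns model and curves.

    Spectra are max-normalized (and right-padded to ``input_length`` if
    shorter); weights, shuffling and hence the final model are deterministic
    under ``config.seed``.  Raises on NaN loss with the failing epoch index.
    """
    config = config or ClassifierConfig()
    model = SpectrumClassifier(config)
    Xtr = _normalize_spectra(_pad_to_length(train.spectra, config.input_length))
    ytr = train.labels
    if valid is not None and len(valid):
        Xva = _normalize_spectra(_pad_to_length(valid.spectra, config.input_length))
        yva = valid.labels
    else:
        Xva = yva = None

    rng = np.random.default_rng(config.seed + 1)  # shuffling stream
    report = ClassifierReport()
    n = len(ytr)
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads = model._loss_and_grads(Xtr[batch], ytr[batch])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
            model._adam_step(grads, lr)
            epoch_losses.append(loss)
        report.train_loss.append(float(np.mean(epoch_losses)))
        if Xva is not None:
            report.valid_loss.append(model.mean_loss(Xva, yva))
    return model, report


def evaluate(
    model: SpectrumClassifier, test: LabeledSpectrumDataset
) -> ClassifierReport:
    """Confusion matrix (rows = true, cols = predicted) and accuracy on a test set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test.spectra)
    k = model.config.n_classes
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(test.labels, pred):
        confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    return ClassifierReport(confusion=confusion, accuracy=accuracy)


def predict_component_labels(
    H: np.ndarray, model: SpectrumClassifier
) -> np.ndarray:
    """Classify each NMF feature-matrix row as 0/1/2 (interference/BZD/EBZD)."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise DimensionalError("H must be a matrix")
    return model.predict(H)
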
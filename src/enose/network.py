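"""Feed-forward classifier for the 32-parameter e-nose features.

Architecture: 32 inputs -> feature normalization (z-score fitted on the
training set only) -> dense 64 -> 32 -> 16, all rectified-linear ->
dense 2 softmax giving per-class probabilities (0 = benign hyperplasia,
1 = prostate cancer).

Training is plain mini-batch stochastic gradient descent with momentum 0.9,
base learning rate 1e-3 under per-update inverse-time decay
``lr_t = lr0 / (1 + decay * t)`` (decay 1e-7), categorical cross-entropy
loss, batch size 32.  Class weights multiply each sample's loss by a
label-dependent factor, trading precision for recall on the critical
(cancer) class.  Everything is seeded, so two runs with the same seed are
bitwise identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

_NORM_EPS = 1e-8


class NetworkError(ValueError):
    """Invalid network configuration or input."""


@dataclass(frozen=True)
class NetworkConfig:
    input_width: int = 32
    hidden_widths: tuple[int, ...] = (64, 32, 16)
    output_width: int = 2
    learning_rate: float = 1e-3
    decay: float = 1e-7
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 1280
    class_weights: dict[int, float] = field(default_factory=lambda: {0: 1.0, 1: 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        widths = (self.input_width, *self.hidden_widths, self.output_width)
        if any(w <= 0 for w in widths):
            raise NetworkError("all layer widths must be positive")
        if self.epochs < 1:
            raise NetworkError("epochs must be >= 1")
        if self.batch_size < 1:
            raise NetworkError("batch_size must be >= 1")
        if any(w <= 0 for w in self.class_weights.values()):
            raise NetworkError("class weights must be positive")

    @property
    def layer_widths(self) -> tuple[int, ...]:
        return (self.input_width, *self.hidden_widths, self.output_width)

    @property
    def dense_parameter_count(self) -> int:
        """Weights + biases over the dense layers (normalization excluded)."""
        w = self.layer_widths
        return sum(w[i] * w[i + 1] + w[i + 1] for i in range(len(w) - 1))


class MLPModel:
    """Dense network state: weights, optional normalization statistics, history."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.layer_widths
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.norm_mean: np.ndarray | None = None
        self.norm_scale: np.ndarray | None = None
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        self.updates_applied = 0

    # -- inference ---------------------------------------------------------

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return X
        return (X - self.norm_mean) / self.norm_scale

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Hidden activations and softmax probabilities."""
        activations = [self._normalize(X)]
        h = activations[0]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            activations.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return activations, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_width:
            raise NetworkError(
                f"expected (n, {self.config.input_width}) features, got {X.shape}"
            )
        return self._forward(X)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax labels; exact probability ties resolve to class 0."""
        return np.argmax(self.predict_proba(X), axis=1)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Serialize config, weights, normalization statistics and history
        as a single JSON document (the network is small enough for text)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["hidden_widths"] = list(self.config.hidden_widths)
        cfg["class_weights"] = {str(k): v for k, v in self.config.class_weights.items()}
        doc = {
            "config": cfg,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "norm_mean": None if self.norm_mean is None else self.norm_mean.tolist(),
            "norm_scale": None if self.norm_scale is None else self.norm_scale.tolist(),
            "history": self.history,
            "updates_applied": self.updates_applied,
        }
        (directory / "model.json").write_text(json.dumps(doc))

    @classmethod
    def load(cls, directory: str | Path) -> "MLPModel":
        doc = json.loads((Path(directory) / "model.json").read_text())
        cfg = doc["config"]
        cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
        cfg["class_weights"] = {int(k): v for k, v in cfg["class_weights"].items()}
        model = cls(NetworkConfig(**cfg))
        model.weights = [np.asarray(w) for w in doc["weights"]]
        model.biases = [np.asarray(b) for b in doc["biases"]]
        if doc["norm_mean"] is not None:
            model.norm_mean = np.asarray(doc["norm_mean"])
            model.norm_scale = np.asarray(doc["norm_scale"])
        model.history = doc["history"]
        model.updates_applied = doc["updates_applied"]
        return model


def build_model(config: NetworkConfig = NetworkConfig()) -> MLPModel:
    """Fresh network with Glorot-uniform weights and zero biases (seeded)."""
    return MLPModel(config)


def one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.min() < 0 or y.max() >= n_classes:
        raise NetworkError(f"labels must lie in [0, {n_classes})")
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def train(model: MLPModel, X: np.ndarray, y: np.ndarray) -> MLPModel:
    """Fit the network in place and return it.

    Normalization statistics (per-feature mean and standard deviation) are
    computed from the training matrix only, never updated afterwards.
    Sample order is reshuffled every epoch with the configured seed; the
    batch remainder is kept as a short final batch.  Per-epoch training
    loss and accuracy are appended to ``model.history``.
    """
    cfg = model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != cfg.input_width:
        raise NetworkError(f"expected (n, {cfg.input_width}) features, got {X.shape}")
    if X.shape[0] == 0:
        raise NetworkError("training set is empty")
    Y = one_hot(y, cfg.output_width)
    sample_w = np.array([cfg.class_weights.get(int(c), 1.0) for c in y])

    model.norm_mean = X.mean(axis=0)
    scale = X.std(axis=0)
    model.norm_scale = np.where(scale < _NORM_EPS, 1.0, scale)

    rng = np.random.default_rng(cfg.seed + 1)  # decouple shuffling from init
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    n = X.shape[0]

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb, wb = X[idx], Y[idx], sample_w[idx]
            acts, probs = model._forward(xb)
            ce = -np.sum(yb * np.log(np.clip(probs, 1e-12, None)), axis=1)
            loss = float(np.mean(wb * ce))
            if not np.isfinite(loss):
                raise NetworkError(
                    f"loss became non-finite at update {model.updates_applied}"
                )
            epoch_loss += loss * idx.size
            epoch_correct += int(np.sum(np.argmax(probs, axis=1) == np.argmax(yb, axis=1)))

            # backprop: d(weighted CCE)/dlogits = w * (p - y), averaged over batch
            delta = (probs - yb) * wb[:, None] / idx.size
            grads_w = []
            grads_b = []
            for layer in range(len(model.weights) - 1, -1, -1):
                grads_w.append(acts[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ model.weights[layer].T) * (acts[layer] > 0)
            grads_w.reverse()
            grads_b.reverse()

            lr = cfg.learning_rate / (1.0 + cfg.decay * model.updates_applied)
            for k in range(len(model.weights)):
                vel_w[k] = cfg.momentum * vel_w[k] - lr * grads_w[k]
                vel_b[k] = cfg.momentum * vel_b[k] - lr * grads_b[k]
                model.weights[k] += vel_w[k]
                model.biases[k] += vel_b[k]
            model.updates_applied += 1
        model.history["loss"].append(epoch_loss / n)
        model.history["accuracy"].append(epoch_correct / n)
    return model


def fit(
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig = NetworkConfig(),
) -> MLPModel:
    """Convenience: build + train in one call."""
    return train(build_model(config), X, y)
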
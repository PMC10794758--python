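"""A small feedforward binary classifier trained with binary cross-entropy.

The network is deliberately minimal: z-scored inputs, one (configurable)
hidden layer defaulting to width max(8, 2*input_dim), ReLU or tanh
activation, a single sigmoid output unit, and plain seeded mini-batch
gradient descent on the mean binary cross-entropy

    Loss(y, p) = -y*log(p) - (1 - y)*log(1 - p),

with p clipped to [eps, 1-eps], eps = 1e-12.  Everything is pure numpy so
that training is deterministic given the seed and the analytic gradients
can be verified against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EPS = 1e-12


@dataclass(frozen=True)
class MLPConfig:
    input_dim: int
    hidden_layers: tuple[int, ...] | None = None  # None -> (max(8, 2*input_dim),)
    activation: str = "relu"
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    standardize: bool = True

    def resolved_hidden(self) -> tuple[int, ...]:
        if self.hidden_layers is not None:
            return tuple(self.hidden_layers)
        return (max(8, 2 * self.input_dim),)

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if any(w < 1 for w in self.resolved_hidden()):
            raise ValueError("all hidden widths must be >= 1")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")


@dataclass
class TrainedModel:
    config: MLPConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                "input_dim": self.config.input_dim,
                "hidden_layers": list(self.config.resolved_hidden()),
                "activation": self.config.activation,
                "learning_rate": self.config.learning_rate,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "seed": self.config.seed,
                "standardize": self.config.standardize,
            },
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "loss_history": self.loss_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        cfg = MLPConfig(
            input_dim=d["config"]["input_dim"],
            hidden_layers=tuple(d["config"]["hidden_layers"]),
            activation=d["config"]["activation"],
            learning_rate=d["config"]["learning_rate"],
            epochs=d["config"]["epochs"],
            batch_size=d["config"]["batch_size"],
            seed=d["config"]["seed"],
            standardize=d["config"]["standardize"],
        )
        return cls(
            config=cfg,
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_sd=np.asarray(d["scaler_sd"]),
            loss_history=list(d["loss_history"]),
        )


def bce_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clipping at 1e-12."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    p = np.clip(y_pred, EPS, 1 - EPS)
    return float(np.mean(-y_true * np.log(p) - (1 - y_true) * np.log(1 - p)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _activation(name: str):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)
    return np.tanh, lambda z: 1.0 - np.tanh(z) ** 2


def init_parameters(config: MLPConfig) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Seeded He-style initialisation (small-variance Gaussian), zero biases."""
    rng = np.random.default_rng(config.seed)
    sizes = [config.input_dim, *config.resolved_hidden(), 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def forward(
    X: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    activation: str,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Forward pass; returns probabilities plus cached pre/post activations."""
    act, _ = _activation(activation)
    a = X
    pre, post = [], [X]
    for i, (w, b) in enumerate(zip(weights, biases)):
        z = a @ w + b
        pre.append(z)
        a = _sigmoid(z) if i == len(weights) - 1 else act(z)
        post.append(a)
    return a[:, 0], pre, post


def loss_and_grads(
    X: np.ndarray,
    y: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    activation: str,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean BCE and its analytic gradients via backpropagation.

    With a sigmoid output the gradient at the output pre-activation is
    (p - y)/n, which stays exact under the loss's probability clipping for
    any p reachable in finite arithmetic.
    """
    n = len(y)
    probs, pre, post = forward(X, weights, biases, activation)
    loss = bce_loss(y, probs)
    _, dact = _activation(activation)
    delta = ((probs - y) / n)[:, None]
    gw = [np.empty_like(w) for w in weights]
    gb = [np.empty_like(b) for b in biases]
    for i in reversed(range(len(weights))):
        gw[i] = post[i].T @ delta
        gb[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ weights[i].T) * dact(pre[i - 1])
    return loss, gw, gb


def train(X: np.ndarray, y: np.ndarray, config: MLPConfig) -> TrainedModel:
    """Mini-batch gradient descent on BCE; deterministic given config.seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("y must contain both classes (binary labels 0/1)")
    if X.shape[1] != config.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns, config.input_dim={config.input_dim}")
    for cls in (0.0, 1.0):
        if np.sum(y == cls) < 2:
            raise ValueError("need at least 2 rows per class")

    if config.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = (X - mean) / sd

    weights, biases = init_parameters(config)
    rng = np.random.default_rng(config.seed + 1)
    n = len(y)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            _, gw, gb = loss_and_grads(Xs[idx], y[idx], weights, biases, config.activation)
            for i in range(len(weights)):
                weights[i] -= config.learning_rate * gw[i]
                biases[i] -= config.learning_rate * gb[i]
        probs, _, _ = forward(Xs, weights, biases, config.activation)
        history.append(bce_loss(y, probs))
    return TrainedModel(
        config=config,
        weights=weights,
        biases=biases,
        scaler_mean=mean,
        scaler_sd=sd,
        loss_history=history,
    )


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.config.input_dim}"
        )
    Xs = (X - model.scaler_mean) / model.scaler_sd
    probs, _, _ = forward(Xs, model.weights, model.biases, model.config.activation)
    return np.clip(probs, EPS, 1 - EPS)


def predict(model: TrainedModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (predict_proba(model, X) > threshold).astype(int)


def stratified_split(
    y: np.ndarray, test_frac: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test index split preserving class ratio."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_test = int(round(test_frac * len(idx)))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return (
        rng.permutation(np.concatenate(train_idx)),
        rng.permutation(np.concatenate(test_idx)),
    )
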
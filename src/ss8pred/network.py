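"""Single-hidden-layer feed-forward networks and their training loop.

Both prediction phases use the same architecture: a fully connected
network with one sigmoidal hidden layer (stage 1: 450 -> 225 -> 8,
stage 2: 135 -> 68 -> 8) trained by mini-batch gradient descent with
momentum to predict the state of the residue at the window center.
The default loss is softmax cross-entropy; a sigmoid-output
squared-error variant is available behind a flag. Early stopping
monitors Q8 (per-residue accuracy) on an explicit validation set.

Everything is plain numpy and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabets import N_SS8, SS8_ORDER, TIEBREAK_RANK

__all__ = [
    "NetworkSpec",
    "Network",
    "TrainingRun",
    "init_network",
    "train_network",
    "argmax_state",
    "argmax_states",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one phase's network."""

    input_width: int
    hidden_width: int
    output_width: int = N_SS8
    loss: str = "cross_entropy"  # or "squared_error" (sigmoid output)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_width < 1 or self.hidden_width < 1 or self.output_width < 1:
            raise ValueError("network widths must be positive")
        if self.loss not in ("cross_entropy", "squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainingRun:
    """Hyperparameters and per-epoch history of one training."""

    epochs: int = 300
    learning_rate: float = 0.01
    batch_size: int = 256
    early_stop_patience: int = 10
    momentum: float = 0.9
    lr_decay: float = 1.0  # per-epoch multiplicative decay (1.0 = constant)
    optimizer: str = "sgd"  # "sgd" (momentum) or "adam"
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """Weights of a single-hidden-layer network."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        # symmetric small-scale (Glorot-uniform) initialization
        r1 = np.sqrt(6.0 / (spec.input_width + spec.hidden_width))
        r2 = np.sqrt(6.0 / (spec.hidden_width + spec.output_width))
        self.W1 = rng.uniform(-r1, r1, size=(spec.input_width, spec.hidden_width))
        self.b1 = np.zeros(spec.hidden_width)
        self.W2 = rng.uniform(-r2, r2, size=(spec.hidden_width, spec.output_width))
        self.b2 = np.zeros(spec.output_width)

    @property
    def n_parameters(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def parameters(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def copy_weights_from(self, other: "Network") -> None:
        for mine, theirs in zip(self.parameters(), other.parameters()):
            mine[...] = theirs

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (hidden activations, output probabilities)."""
        H = _logistic(X @ self.W1 + self.b1)
        Z = H @ self.W2 + self.b2
        if self.spec.loss == "cross_entropy":
            Y = _softmax(Z)
        else:
            Y = _logistic(Z)
        return H, Y

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-row output distribution (sigmoid outputs are normalized)."""
        _, Y = self.forward(X)
        if self.spec.loss == "squared_error":
            Y = Y / np.maximum(Y.sum(axis=1, keepdims=True), 1e-12)
        return Y


def init_network(spec: NetworkSpec) -> Network:
    """Create a network with seeded symmetric small-scale weights."""
    return Network(spec)


def _batch_grad(
    net: Network, X: np.ndarray, T: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """Mean loss and gradients on one batch; T is one-hot targets."""
    n = X.shape[0]
    H, Y = net.forward(X)
    if net.spec.loss == "cross_entropy":
        loss = float(-np.sum(T * np.log(np.maximum(Y, 1e-12))) / n)
        dZ = (Y - T) / n
    else:
        loss = float(np.sum((Y - T) ** 2) / n)
        dZ = 2.0 * (Y - T) * Y * (1.0 - Y) / n
    gW2 = H.T @ dZ
    gb2 = dZ.sum(axis=0)
    dH = dZ @ net.W2.T * H * (1.0 - H)
    gW1 = X.T @ dH
    gb1 = dH.sum(axis=0)
    return loss, [gW1, gb1, gW2, gb2]


def train_network(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    run: TrainingRun,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    seed: int = 0,
    class_weights: np.ndarray | None = None,
) -> TrainingRun:
    """Train in place by mini-batch SGD with momentum.

    ``y`` holds integer state indices. When a validation set is given,
    early stopping keeps the weights with the best validation Q8 and
    halts after ``early_stop_patience`` epochs without improvement.
    A zero-epoch run returns the network unchanged. History entries
    record (epoch, mean training loss, validation Q8).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature/label count mismatch")
    K = net.spec.output_width
    T = np.zeros((X.shape[0], K))
    T[np.arange(X.shape[0]), y] = 1.0
    if class_weights is not None:
        T = T * np.asarray(class_weights, dtype=float)[y][:, None]

    rng = np.random.default_rng(seed)
    velocity = [np.zeros_like(p) for p in net.parameters()]
    second = [np.zeros_like(p) for p in net.parameters()]
    best_q8 = -np.inf
    best = None
    stall = 0
    step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for epoch in range(run.epochs):
        lr = run.learning_rate * run.lr_decay**epoch
        order = rng.permutation(X.shape[0])
        losses = []
        for start in range(0, X.shape[0], run.batch_size):
            idx = order[start : start + run.batch_size]
            loss, grads = _batch_grad(net, X[idx], T[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; lower the learning rate"
                )
            losses.append(loss)
            if run.optimizer == "adam":
                step += 1
                for p, m, v, g in zip(net.parameters(), velocity, second, grads):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g * g
                    mhat = m / (1 - beta1**step)
                    vhat = v / (1 - beta2**step)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
            else:
                for p, v, g in zip(net.parameters(), velocity, grads):
                    v *= run.momentum
                    v -= lr * g
                    p += v
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if X_val is not None and len(X_val):
            pred = net.predict_proba(X_val).argmax(axis=1)
            val_q8 = float((pred == y_val).mean() * 100.0)
            entry["val_q8"] = val_q8
            if val_q8 > best_q8 + 1e-12:
                best_q8 = val_q8
                best = [p.copy() for p in net.parameters()]
                stall = 0
            else:
                stall += 1
        run.history.append(entry)
        if X_val is not None and stall >= run.early_stop_patience:
            break

    if best is not None:
        for p, b in zip(net.parameters(), best):
            p[...] = b
    return run


def argmax_states(probs: np.ndarray) -> np.ndarray:
    """Vectorized tie-broken argmax over rows of an N x 8 matrix."""
    probs = np.asarray(probs, dtype=float)
    if np.isnan(probs).all(axis=-1).any():
        raise ValueError("all-NaN probability row")
    # lexicographic: maximal probability first, then lowest tie-break rank
    order = np.argsort(TIEBREAK_RANK)  # state indices from best to worst priority
    reordered = probs[..., order]
    best = np.nanargmax(reordered, axis=-1)
    return order[best]


def argmax_state(probs: np.ndarray) -> str:
    """State letter of maximal probability.

    Exact ties are broken by the fixed frequency-informed priority
    H > E > C > T > G > S > B > I.
    """
    return SS8_ORDER[int(argmax_states(np.asarray(probs)[None, :])[0])]
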
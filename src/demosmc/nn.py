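"""A small, fully seedable multilayer perceptron in NumPy.

No deep-learning framework is available in the target environment, so the
network used to summarize cSFS vectors is implemented directly: dense
ReLU layers, inter-layer dropout, an input Gaussian-noise layer followed
by rectification, Adam/Nadam optimizers, categorical cross-entropy or
log-cosh losses, plateau-halved learning rate, early stopping and
best-checkpoint retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = ["MLP", "TrainingLog"]


def _he_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def categorical_cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def log_cosh(pred: np.ndarray, target: np.ndarray) -> float:
    d = pred - target
    # numerically stable log(cosh(d))
    return float((np.abs(d) + np.log1p(np.exp(-2.0 * np.abs(d))) - np.log(2.0)).mean())


@dataclass
class TrainingLog:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    learning_rates: List[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch] if self.best_epoch >= 0 else np.inf


class _Optimizer:
    """Adam / Nadam with per-parameter moment state."""

    def __init__(self, kind: str, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if kind not in ("adam", "nadam"):
            raise ValueError(f"unknown optimizer {kind!r}")
        self.kind = kind
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: Dict[int, np.ndarray] = {}
        self.v: Dict[int, np.ndarray] = {}

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            if i not in self.m:
                self.m[i] = np.zeros_like(p)
                self.v[i] = np.zeros_like(p)
            m = self.m[i] = b1 * self.m[i] + (1 - b1) * g
            v = self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            if self.kind == "nadam":
                m_hat = b1 * m_hat + (1 - b1) * g / (1 - b1 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class MLP:
    """Feed-forward network with ReLU hidden layers.

    ``head`` is ``"softmax"`` (classification, cross-entropy) or
    ``"linear"`` (regression, log-cosh).  The input pipeline divides by a
    fixed per-feature scale, then (during training only) adds Gaussian
    noise and rectifies.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        head: str,
        hidden: Sequence[int] = (256, 128, 64, 32),
        dropout: float = 0.01,
        noise_sd: float = 0.05,
        seed: int = 0,
    ):
        if head not in ("softmax", "linear"):
            raise ValueError(f"unknown head {head!r}")
        self.head = head
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.noise_sd = noise_sd
        self.rng = np.random.default_rng(seed)
        sizes = [n_in, *hidden, n_out]
        self.weights = [
            _he_init(self.rng, sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.feature_scale = np.ones(n_in)

    # ------------------------------------------------------------------
    def _forward(self, x: np.ndarray, training: bool):
        x = np.asarray(x, dtype=float) / self.feature_scale
        if training:
            x = x + self.rng.normal(0.0, self.noise_sd, size=x.shape)
        x = np.maximum(x, 0.0)
        activations = [x]
        masks = []
        h = x
        n_hidden = len(self.hidden)
        for li in range(n_hidden):
            z = h @ self.weights[li] + self.biases[li]
            h = np.maximum(z, 0.0)
            if training and self.dropout > 0:
                keep = 1.0 - self.dropout
                mask = (self.rng.random(h.shape) < keep) / keep
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            activations.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        if self.head == "softmax":
            out = softmax(out)
        return out, activations, masks

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out, _, _ = self._forward(x, training=False)
        return out

    def loss(self, pred: np.ndarray, target: np.ndarray) -> float:
        if self.head == "softmax":
            return categorical_cross_entropy(pred, target)
        return log_cosh(pred, target)

    # ------------------------------------------------------------------
    def _backward(self, out, activations, masks, target):
        n = out.shape[0]
        if self.head == "softmax":
            delta = (out - target) / n           # d CE / d logits
        else:
            delta = np.tanh(out - target) / (n * out.shape[1])  # d log-cosh
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        grads_w[-1] = activations[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        for li in range(len(self.hidden) - 1, -1, -1):
            delta = delta @ self.weights[li + 1].T
            if masks[li] is not None:
                delta = delta * masks[li]
            delta = delta * (activations[li + 1] > 0)
            grads_w[li] = activations[li].T @ delta
            grads_b[li] = delta.sum(axis=0)
        return grads_w, grads_b

    # ------------------------------------------------------------------
    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        optimizer: str = "adam",
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 1000,
        lr_patience: int = 10,
        early_stop_patience: int = 100,
        set_feature_scale: bool = True,
    ) -> TrainingLog:
        """Train with per-epoch shuffling, plateau LR halving, early
        stopping, and restoration of the best-validation-loss weights."""
        x_train = np.asarray(x_train, dtype=float)
        y_train = np.asarray(y_train, dtype=float)
        if not (np.isfinite(x_train).all() and np.isfinite(y_train).all()):
            raise ValueError("non-finite training data")
        if x_train.shape[0] == 0:
            raise ValueError("empty training set")
        if set_feature_scale:
            scale = x_train.max(axis=0)
            self.feature_scale = np.where(scale > 0, scale, 1.0)

        opt = _Optimizer(optimizer, learning_rate)
        log = TrainingLog()
        best_val = np.inf
        best_weights = None
        epochs_since_best = 0
        epochs_since_lr = 0
        n = x_train.shape[0]
        for epoch in range(max_epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                out, acts, masks = self._forward(x_train[idx], training=True)
                epoch_loss += self.loss(out, y_train[idx]) * len(idx)
                gw, gb = self._backward(out, acts, masks, y_train[idx])
                opt.lr = learning_rate
                opt.step(self.weights + self.biases, gw + gb)
            val_pred = self.predict(x_val)
            val_loss = self.loss(val_pred, np.asarray(y_val, dtype=float))
            log.train_loss.append(epoch_loss / n)
            log.val_loss.append(val_loss)
            log.learning_rates.append(learning_rate)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_weights = ([w.copy() for w in self.weights],
                                [b.copy() for b in self.biases])
                log.best_epoch = epoch
                epochs_since_best = 0
                epochs_since_lr = 0
            else:
                epochs_since_best += 1
                epochs_since_lr += 1
                if epochs_since_lr >= lr_patience:
                    learning_rate *= 0.5
                    epochs_since_lr = 0
                if epochs_since_best >= early_stop_patience:
                    log.stopped_epoch = epoch
                    break
        if best_weights is not None:
            self.weights, self.biases = best_weights
        if log.stopped_epoch < 0:
            log.stopped_epoch = len(log.val_loss) - 1
        return log

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Serialize weights + input scaling to an .npz archive."""
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        arrays["feature_scale"] = self.feature_scale
        arrays["meta"] = np.array(
            [len(self.hidden), self.dropout, self.noise_sd], dtype=float
        )
        arrays["head"] = np.array([0 if self.head == "softmax" else 1])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MLP":
        with np.load(path) as data:
            n_hidden = int(data["meta"][0])
            weights = [data[f"w{i}"] for i in range(n_hidden + 1)]
            biases = [data[f"b{i}"] for i in range(n_hidden + 1)]
            net = cls(
                n_in=weights[0].shape[0],
                n_out=weights[-1].shape[1],
                head="softmax" if int(data["head"][0]) == 0 else "linear",
                hidden=tuple(w.shape[1] for w in weights[:-1]),
                dropout=float(data["meta"][1]),
                noise_sd=float(data["meta"][2]),
            )
            net.weights = weights
            net.biases = biases
            net.feature_scale = data["feature_scale"]
        return net
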
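"""CNN classifier for 32 x 32 connectivity matrices, implemented in NumPy.

Architecture (two convolution blocks, then a dense head):

    conv(32 filters, 5x5, same) -> batch-norm -> max-pool(2x2) -> dropout(0.4)
    -> conv(64 filters, 5x5, same) -> batch-norm -> max-pool(2x2) -> dropout(0.4)
    -> flatten -> dense(128, ReLU) -> dense(2, softmax)

Training uses Adam (learning rate 1e-4), categorical cross-entropy,
batch size 32, a stratified 80/20 train/test split with part of the
training portion held out for validation-based early stopping.  All
randomness (initialisation, dropout masks, batch shuffling, splits)
derives from a single integer seed, so a fixed seed reproduces the
training history and the predictions bit-for-bit on one machine.

No deep-learning framework is assumed: convolution is an im2col matrix
product with an explicit backward pass, verified against numeric
gradients in the test-suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .io import LabeledDataset

__all__ = ["ModelConfig", "SplitSpec", "CNNClassifier", "build_model", "train", "predict"]


@dataclass(frozen=True)
class ModelConfig:
    input_shape: tuple[int, int] = (32, 32)
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel_size: int = 5
    pool_size: int = 2
    dropout: float = 0.4
    dense_units: int = 128
    n_classes: int = 2
    batch_size: int = 32
    learning_rate: float = 1e-4
    epochs: int = 100
    patience: int = 10
    seed: int = 0
    dtype: str = "float32"  # float64 only needed for numeric gradient checks

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd (same padding)")
        if self.n_classes != 2:
            raise ValueError("binary high/low classification only")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split; a slice of train is held out for
    early-stopping validation."""

    test_size: float = 0.2
    val_fraction: float = 0.2  # of the training portion
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_size < 1 or not 0 <= self.val_fraction < 1:
            raise ValueError("split proportions must lie in (0, 1)")


# ---------------------------------------------------------------- layers


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    d = dcols.reshape(n, c, k, k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class _Layer:
    name = "layer"
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv2D(_Layer):
    """Same-padded stride-1 convolution via im2col."""

    name = "conv"

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.pad, self.in_ch = k, k // 2, in_ch
        fan_in = in_ch * k * k
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in)),
            "b": np.zeros(out_ch),
        }

    def forward(self, x, train):
        self._x_shape = x.shape
        n, _, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)  # (n, ckk, hw)
        # fold the batch into columns: one large GEMM instead of n small ones
        self._colmat = np.ascontiguousarray(cols.transpose(1, 0, 2)).reshape(
            cols.shape[1], n * h * w)
        out = self.params["W"] @ self._colmat + self.params["b"][:, None]
        return out.reshape(-1, n, h * w).transpose(1, 0, 2).reshape(n, -1, h, w)

    def backward(self, dout):
        n, f, h, w = dout.shape
        dmat = np.ascontiguousarray(
            dout.reshape(n, f, h * w).transpose(1, 0, 2)).reshape(f, n * h * w)
        self.grads["W"] = dmat @ self._colmat.T
        self.grads["b"] = dmat.sum(axis=1)
        dcols = (self.params["W"].T @ dmat).reshape(-1, n, h * w).transpose(1, 0, 2)
        return _col2im(dcols, self._x_shape, self.k, self.pad)


class _BatchNorm(_Layer):
    """Per-channel batch normalisation over (N, H, W)."""

    name = "batchnorm"

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(n_ch), "beta": np.zeros(n_ch)}
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mu[None, :, None, None]) / self._std
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.params["gamma"][None, :, None, None] * self._xhat + \
            self.params["beta"][None, :, None, None]

    def backward(self, dout):
        axes = (0, 2, 3)
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"][None, :, None, None]
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) / std
        return dx


class _MaxPool(_Layer):
    name = "maxpool"

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        s = self.size
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // s, s, w // s, s)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # split gradient equally among (rare) ties
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._x_shape = x.shape
        return out

    def backward(self, dout):
        s = self.size
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(self._x_shape)


class _Dropout(_Layer):
    name = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
                      ).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Flatten(_Layer):
    name = "flatten"

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense(_Layer):
    name = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        super().__init__()
        self.activation = activation
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x, train):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * (self._z > 0)
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, layers: list[_Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers, self.lr = layers, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


# ----------------------------------------------------------------- model


class CNNClassifier:
    """The two-block convolutional classifier (see module docstring)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
        h, w = config.input_shape
        k, p = config.kernel_size, config.pool_size
        flat = (h // (p * p)) * (w // (p * p)) * config.conv2_filters
        self.layers: list[_Layer] = [
            _Conv2D(1, config.conv1_filters, k, rng),
            _BatchNorm(config.conv1_filters),
            _MaxPool(p),
            _Dropout(config.dropout, self._dropout_rng),
            _Conv2D(config.conv1_filters, config.conv2_filters, k, rng),
            _BatchNorm(config.conv2_filters),
            _MaxPool(p),
            _Dropout(config.dropout, self._dropout_rng),
            _Flatten(),
            _Dense(flat, config.dense_units, rng, activation="relu"),
            _Dense(config.dense_units, config.n_classes, rng),
        ]
        dt = np.dtype(config.dtype)
        for lay in self.layers:
            lay.params = {k: v.astype(dt) for k, v in lay.params.items()}
            if isinstance(lay, _BatchNorm):
                lay.running_mean = lay.running_mean.astype(dt)
                lay.running_var = lay.running_var.astype(dt)
        self.history: dict[str, list[float]] = {}
        self.is_trained = False

    # -- introspection -------------------------------------------------
    @property
    def layer_names(self) -> list[str]:
        return [lay.name for lay in self.layers]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for lay in self.layers for p in lay.params.values())

    # -- forward / backward --------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for lay in reversed(self.layers):
            d = lay.backward(d)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray, train: bool = True) -> float:
        """Mean cross-entropy on one batch; leaves gradients in the layers."""
        loss, _ = self._train_batch(x, y, train)
        return loss

    def _train_batch(self, x: np.ndarray, y: np.ndarray, train: bool = True
                     ) -> tuple[float, int]:
        """One forward/backward pass; returns (mean loss, n correct)."""
        logits = self._forward(x, train)
        probs = _softmax(logits)
        n = x.shape[0]
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        self._backward(dlogits / n)
        return float(loss), int(np.sum(probs.argmax(axis=1) == y))

    # -- inference ------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities, rows summing to 1; dropout off, batch-norm
        in inference mode."""
        x = _as_input(x, self.config)
        return _softmax(self._forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Hard 0/1 labels (1 = the positive "high" class)."""
        return self.predict_proba(x).argmax(axis=1)

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {}
        for i, lay in enumerate(self.layers):
            for k, v in lay.params.items():
                arrays[f"{i}:{k}"] = v
            if isinstance(lay, _BatchNorm):
                arrays[f"{i}:running_mean"] = lay.running_mean
                arrays[f"{i}:running_var"] = lay.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"config": asdict(self.config), "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model = cls(ModelConfig(**cfg))
        with np.load(path.with_suffix(".npz")) as npz:
            for i, lay in enumerate(model.layers):
                for k in lay.params:
                    lay.params[k] = npz[f"{i}:{k}"]
                if isinstance(lay, _BatchNorm):
                    lay.running_mean = npz[f"{i}:running_mean"]
                    lay.running_var = npz[f"{i}:running_var"]
        model.history = meta["history"]
        model.is_trained = True
        return model


def _as_input(x, config: ModelConfig) -> np.ndarray:
    """Coerce matrices / datasets / arrays to (N, 1, H, W) float input."""
    if isinstance(x, LabeledDataset):
        x, _ = x.to_arrays()
    elif isinstance(x, (list, tuple)):
        x = np.stack([getattr(m, "values", m) for m in x])
    x = np.asarray(x, dtype=config.dtype)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    h, w = config.input_shape
    if x.shape[1:] != (1, h, w):
        raise ValueError(f"expected input (*, 1, {h}, {w}), got {x.shape}")
    return x


def build_model(config: ModelConfig | None = None) -> CNNClassifier:
    """Fresh (untrained) classifier from a config."""
    return CNNClassifier(config or ModelConfig())


def train(
    model: CNNClassifier,
    dataset: LabeledDataset | tuple[np.ndarray, np.ndarray],
    split: SplitSpec | None = None,
) -> CNNClassifier:
    """Train on the train partition of a stratified split.

    Records per-epoch train/validation loss and accuracy in
    ``model.history`` and keeps the parameters of the best validation
    epoch (early stopping, patience from the model config).  The test
    partition is never touched during training; its indices are stored
    on the model as ``test_indices`` for later evaluation.

    Matrices are expected to be PLVs already in [0, 1]; no further
    normalisation is applied (asserted here).
    """
    split = split or SplitSpec(seed=model.config.seed)
    if isinstance(dataset, LabeledDataset):
        x, y = dataset.to_arrays()
    else:
        x, y = dataset
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("inputs must already lie in [0, 1] (PLV scale)")

    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=split.test_size, stratify=y, random_state=split.seed)
    if split.val_fraction > 0:
        tr_idx, val_idx = train_test_split(
            train_idx, test_size=split.val_fraction,
            stratify=y[train_idx], random_state=split.seed)
    else:
        tr_idx, val_idx = train_idx, train_idx
    model.test_indices = test_idx

    xin = _as_input(x, model.config)
    cfg = model.config
    opt = _Adam(model.layers, cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]))
    hist = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_val, best_params, patience_left = np.inf, None, cfg.patience

    for _epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(tr_idx)
        losses, n_correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss, correct = model._train_batch(xin[batch], y[batch], train=True)
            losses.append(loss)
            n_correct += correct
            opt.step()
        hist["loss"].append(float(np.mean(losses)))
        # training accuracy accumulated over the dropout/batch-stat batches,
        # as frameworks report it; validation uses inference mode below
        hist["accuracy"].append(n_correct / len(order))
        vprob = model.predict_proba(xin[val_idx])
        vloss = float(-np.mean(np.log(vprob[np.arange(len(val_idx)), y[val_idx]] + 1e-12)))
        hist["val_loss"].append(vloss)
        hist["val_accuracy"].append(float(np.mean(vprob.argmax(1) == y[val_idx])))
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_params = [
                {k: v.copy() for k, v in lay.params.items()} for lay in model.layers
            ]
            best_stats = [
                (lay.running_mean.copy(), lay.running_var.copy())
                if isinstance(lay, _BatchNorm) else None
                for lay in model.layers
            ]
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    if best_params is not None:
        for lay, params, stats in zip(model.layers, best_params, best_stats):
            lay.params = params
            if stats is not None:
                lay.running_mean, lay.running_var = stats
    model.history = hist
    model.is_trained = True
    return model


def predict(model: CNNClassifier, matrices) -> np.ndarray:
    """Per-item class probabilities (n, 2); columns order (low, high)."""
    return model.predict_proba(matrices)
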
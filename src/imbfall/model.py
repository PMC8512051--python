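"""A small 1D residual convolutional classifier, implemented in NumPy.

The network follows the compact "ResNet10" layout used for inertial
time-series classification: the (channels x timesteps) window passes through
four residual blocks — each two 1x3 convolutions with batch normalization
and ReLU, plus a shortcut connection added elementwise (a 1x1 projection
when the channel count or stride changes) — then global average pooling, a
fully connected layer and a softmax over the two classes, yielding a
posterior probability per window.

Everything here (forward, backward, Adam) is plain NumPy: the model is small
enough that im2col GEMM convolutions train it on a single CPU core in
minutes. Gradients are exact analytic derivatives; a numerical-gradient test
pins them down.

Array convention: activations are (batch, channels, timesteps).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import SplitCorpus, WindowedSample, stack_windows


class ModelError(ValueError):
    pass


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    Defaults: four residual blocks widening 16->32->64->128 with stride-2
    downsampling between blocks, 1x3 kernels, Adam at learning rate 0.001,
    at most 30 epochs, batch size 64.
    """

    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel_width: int = 3
    input_shape: tuple[int, int] = (200, 3)  # (timesteps, channels)
    n_classes: int = 2
    learning_rate: float = 1e-3
    max_epochs: int = 30
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_width % 2 != 1:
            raise ModelError("kernel_width must be odd (symmetric zero padding)")
        if self.n_classes < 2:
            raise ModelError("n_classes must be >= 2")

    @property
    def n_blocks(self) -> int:
        return len(self.channels)


# ---------------------------------------------------------------------------
# Layers. Each caches what its backward pass needs; backward() returns the
# input gradient and fills .grads parallel to .params.
# ---------------------------------------------------------------------------


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}


class Conv1d(Layer):
    """1D cross-correlation with symmetric zero padding ("same" for stride 1)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        fan_in = c_in * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel))
        self.params["b"] = np.zeros(c_out)

    def _l_out(self, l_in: int) -> int:
        return (l_in + 2 * self.pad - self.kernel) // self.stride + 1

    def _im2col(self, xp: np.ndarray, l_out: int) -> np.ndarray:
        n, c_in, _ = xp.shape
        k, s = self.kernel, self.stride
        col = np.empty((n, k * c_in, l_out))
        for a in range(k):
            col[:, a * c_in : (a + 1) * c_in, :] = xp[:, :, a : a + s * l_out : s]
        return col

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c_in, l_in = x.shape
        if c_in != self.c_in:
            raise ModelError(f"expected {self.c_in} input channels, got {c_in}")
        l_out = self._l_out(l_in)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        col = self._im2col(xp, l_out)
        w2 = self.params["W"].transpose(0, 2, 1).reshape(self.c_out, -1)  # (o, k*c)
        y = np.matmul(w2, col) + self.params["b"][:, None]
        if training:
            self._cache = (col, l_in)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, l_in = self._cache
        n = dy.shape[0]
        k, s, c_in = self.kernel, self.stride, self.c_in
        l_out = dy.shape[2]
        w2 = self.params["W"].transpose(0, 2, 1).reshape(self.c_out, -1)
        dw2 = np.einsum("not,nct->oc", dy, col, optimize=True)
        self.grads["W"] = dw2.reshape(self.c_out, k, c_in).transpose(0, 2, 1)
        self.grads["b"] = dy.sum(axis=(0, 2))
        dcol = np.matmul(w2.T, dy)  # (n, k*c_in, l_out)
        dxp = np.zeros((n, c_in, l_in + 2 * self.pad))
        for a in range(k):
            dxp[:, :, a : a + s * l_out : s] += dcol[:, a * c_in : (a + 1) * c_in, :]
        if self.pad:
            return dxp[:, :, self.pad : -self.pad]
        return dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time); running stats for eval."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g = self.params["gamma"][None, :, None]
        b = self.params["beta"][None, :, None]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv[None, :, None]
            self._cache = (xhat, inv)
            return g * xhat + b
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return g * (x - self.running_mean[None, :, None]) * inv[None, :, None] + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n, c, l = dy.shape
        m = n * l
        self.grads["beta"] = dy.sum(axis=(0, 2))
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
        return (inv[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class ResidualBlock:
    """conv -> BN -> ReLU -> conv -> BN, added to the (possibly projected)
    shortcut, then a final ReLU. With a zero residual branch the block reduces
    to ReLU(identity)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv1d(c_in, c_out, kernel, stride, rng)
        self.bn1 = BatchNorm1d(c_out)
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, rng)
        self.bn2 = BatchNorm1d(c_out)
        self.project = c_in != c_out or stride != 1
        if self.project:
            self.proj_conv = Conv1d(c_in, c_out, 1, stride, rng)
            self.proj_bn = BatchNorm1d(c_out)

    def layers(self) -> list[Layer]:
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.project:
            out += [self.proj_conv, self.proj_bn]
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h1 = np.maximum(h, 0.0)
        h2 = self.conv2.forward(h1, training)
        h2 = self.bn2.forward(h2, training)
        if self.project:
            sc = self.proj_bn.forward(self.proj_conv.forward(x, training), training)
        else:
            if h2.shape != x.shape:
                raise ModelError(
                    f"residual shape mismatch {h2.shape} vs {x.shape} without projection"
                )
            sc = x
        pre = h2 + sc
        out = np.maximum(pre, 0.0)
        if training:
            self._cache = (h1 > 0, pre > 0)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask1, mask_out = self._cache
        dpre = dy * mask_out
        dh2 = self.bn2.backward(dpre)
        dh1 = self.conv2.backward(dh2)
        dh = self.bn1.backward(dh1 * mask1)
        dx = self.conv1.backward(dh)
        if self.project:
            dx = dx + self.proj_conv.backward(self.proj_bn.backward(dpre))
        else:
            dx = dx + dpre
        return dx


def residual_block(x: np.ndarray, block: ResidualBlock) -> np.ndarray:
    """Apply one residual block (inference mode) to a (batch, channels, time)
    feature map: ReLU(F(x) + shortcut(x))."""
    return block.forward(x, training=False)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.params["b"] = np.zeros(d_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._cache = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] = dy.T @ x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Losses: each returns (mean loss, gradient w.r.t. logits).
# ---------------------------------------------------------------------------


def cross_entropy_grad(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    n = logits.shape[0]
    p = softmax(logits)
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    w = np.ones(n) if class_weights is None else class_weights[y]
    loss = float(-(w * logp).mean())
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    dlogits = w[:, None] * (p - onehot) / n
    return loss, dlogits


def focal_loss_grad(
    logits: np.ndarray, y: np.ndarray, gamma: float = 2.0, alpha: float = 0.75
) -> tuple[float, np.ndarray]:
    """Focal loss -alpha_t (1 - p_t)^gamma log(p_t); alpha weights the
    minority (label 1) class, 1-alpha the majority."""
    n = logits.shape[0]
    p = softmax(logits)
    pt = np.clip(p[np.arange(n), y], 1e-12, 1.0 - 1e-12)
    at = np.where(y == 1, alpha, 1.0 - alpha)
    one_m = 1.0 - pt
    loss = float((-at * one_m**gamma * np.log(pt)).mean())
    # dL/dp_t, then chain through softmax: dp_t/dz_j = p_t (delta_{jy} - p_j)
    dl_dpt = at * (gamma * one_m ** np.maximum(gamma - 1.0, 0.0) * np.log(pt) - one_m**gamma / pt)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    dlogits = dl_dpt[:, None] * pt[:, None] * (onehot - p) / n
    return loss, dlogits


@dataclass
class LossSpec:
    """Which training loss to minimize: 'cross_entropy' (optionally with
    per-class weights) or 'focal' (gamma, alpha)."""

    name: str = "cross_entropy"
    class_weights: np.ndarray | None = None
    gamma: float = 2.0
    alpha: float = 0.75

    def __call__(self, logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        if self.name == "cross_entropy":
            return cross_entropy_grad(logits, y, self.class_weights)
        if self.name == "focal":
            return focal_loss_grad(logits, y, self.gamma, self.alpha)
        raise ModelError(f"unknown loss {self.name!r}")


# ---------------------------------------------------------------------------
# The classifier.
# ---------------------------------------------------------------------------


class Classifier:
    """Residual 1D conv net: blocks -> global average pooling -> linear -> softmax."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        _, c_in = config.input_shape
        self.blocks: list[ResidualBlock] = []
        prev = c_in
        for i, c in enumerate(config.channels):
            stride = 1 if i == 0 else 2
            self.blocks.append(ResidualBlock(prev, c, config.kernel_width, stride, rng))
            prev = c
        self.head = Linear(prev, config.n_classes, rng)

    # -- parameter plumbing -------------------------------------------------
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.blocks:
            out.extend(b.layers())
        out.append(self.head)
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(layer, BatchNorm1d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for k in layer.params:
                layer.params[k] = state[f"{i}.{k}"].copy()
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for b in self.blocks:
            h = b.forward(h, training)
        self._gap_l = h.shape[2]
        pooled = h.mean(axis=2)
        return self.head.forward(pooled, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.head.backward(dlogits)
        dh = np.repeat(dpooled[:, :, None], self._gap_l, axis=2) / self._gap_l
        for b in reversed(self.blocks):
            dh = b.backward(dh)

    def predict_proba_array(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if x.shape[0] == 0:
            return np.zeros((0, self.config.n_classes))
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward_logits(x[i : i + batch_size], training=False)))
        return np.vstack(out)


def build_network(config: NetworkConfig) -> Classifier:
    """Build the classifier with seeded parameter initialization."""
    return Classifier(config)


class Adam:
    def __init__(self, layers: Sequence[Layer], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers, self.lr, self.b1, self.b2, self.eps = layers, lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, g in layer.grads.items():
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                layer.params[k] -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


def train(
    classifier: Classifier,
    corpus: SplitCorpus,
    config: NetworkConfig | None = None,
    loss: LossSpec | None = None,
    verbose: bool = False,
) -> tuple[Classifier, pd.DataFrame]:
    """Mini-batch Adam training with per-epoch train/validation loss history.

    Returns the classifier restored to the epoch with the best validation
    loss, plus the history (epoch, train_loss, val_loss, val_accuracy).
    Warns (does not fail) on single-class training data with plain
    cross-entropy.
    """
    config = config or classifier.config
    loss = loss or LossSpec()
    x_train, y_train = stack_windows(corpus.train)
    x_val, y_val = stack_windows(corpus.validation)
    if x_train.shape[0] == 0:
        raise ModelError("empty train split")
    if len(np.unique(y_train)) < 2:
        import warnings

        warnings.warn("training data contains a single class", stacklevel=2)

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(classifier.layers(), config.learning_rate)
    history = []
    best_val = np.inf
    best_state = classifier.get_state()
    n = x_train.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = classifier.forward_logits(x_train[idx], training=True)
            batch_loss, dlogits = loss(logits, y_train[idx])
            classifier.backward(dlogits)
            opt.step()
            epoch_losses.append(batch_loss)
        train_loss = float(np.mean(epoch_losses))
        if x_val.shape[0]:
            val_logits_p = classifier.predict_proba_array(x_val)
            logp = np.log(np.clip(val_logits_p, 1e-12, None))
            val_loss, _ = loss(logp, y_val)  # log-probs behave as logits under softmax
            val_acc = float((val_logits_p.argmax(axis=1) == y_val).mean())
        else:
            val_loss, val_acc = train_loss, np.nan
        history.append((epoch, train_loss, val_loss, val_acc))
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}  acc {val_acc:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = classifier.get_state()
    classifier.set_state(best_state)
    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss", "val_accuracy"])
    return classifier, hist


def predict_proba(classifier: Classifier, windows: Sequence[WindowedSample]) -> np.ndarray:
    """Order-preserving per-window class posteriors (rows sum to 1)."""
    x, _ = stack_windows(windows)
    if x.shape[0]:
        expected_c = classifier.config.input_shape[1]
        expected_t = classifier.config.input_shape[0]
        if x.shape[1] != expected_c or x.shape[2] != expected_t:
            raise ModelError(
                f"window shape {x.shape[1:]} does not match configured input "
                f"shape (channels={expected_c}, timesteps={expected_t})"
            )
    return classifier.predict_proba_array(x)


# -- checkpoint io ----------------------------------------------------------


def save_checkpoint(classifier: Classifier, path) -> None:
    import json
    from pathlib import Path

    path = Path(path)
    state = classifier.get_state()
    np.savez(path.with_suffix(".npz"), **state)
    cfg = dataclasses.asdict(classifier.config)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> Classifier:
    import json
    from pathlib import Path

    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["channels"] = tuple(cfg["channels"])
    cfg["input_shape"] = tuple(cfg["input_shape"])
    clf = Classifier(NetworkConfig(**cfg))
    with np.load(path.with_suffix(".npz")) as data:
        clf.set_state({k: data[k] for k in data.files})
    return clf
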
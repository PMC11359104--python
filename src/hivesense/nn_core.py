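"""Minimal feed-forward network core used by the strand and image classifiers.

Implements exactly what the monitoring models need and nothing more: dense
and small convolutional layers, ReLU, softmax cross-entropy (optionally label
smoothed), an L1 (lasso) penalty on dense-layer weights, and Adam.  All
computation is float32 numpy; training is deterministic for a fixed seed up
to floating-point reduction order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError, ShapeError


@dataclass
class TrainConfig:
    """Training recipe shared by both classifiers.

    Adam with lr 0.001, beta1 0.9, beta2 0.999, eps 1e-8; 100 epochs of
    batch-64 updates; an 80/20 train/test split with 10 % of the training
    part held out for per-epoch validation; L1 penalty 0.005 on dense-layer
    weights (strand models; the image classifier defaults to 0).
    """

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 100
    batch_size: int = 64
    train_fraction: float = 0.8
    val_fraction: float = 0.1  # of the training part
    l1_lambda: float = 0.005
    label_smoothing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must be in (0, 1)")
        if not 0 <= self.label_smoothing < 1:
            raise ParameterError("label_smoothing must be in [0, 1)")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    #: True for layers whose weight matrix takes the L1 penalty.
    l1_penalized = False

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    l1_penalized = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: float | None = None):
        super().__init__()
        scale = np.sqrt(2.0 / n_in) if scale is None else scale  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        self._mask = out > 0 if train else None
        return out

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class AvgPoolStem(Layer):
    """Fixed, parameter-free average pooling used as the image down-sampling stem."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x, train):
        n, h, w, c = x.shape
        f = self.factor
        return x.reshape(n, h // f, f, w // f, f, c).mean(axis=(2, 4))

    def backward(self, grad):  # first layer; gradient past it is never used
        f = self.factor
        return np.repeat(np.repeat(grad, f, axis=1), f, axis=2) / (f * f)


class Conv2D(Layer):
    """Valid-mode k x k convolution on NHWC tensors via im2col."""

    l1_penalized = False  # the paper's L1 penalty applies per dense layer

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = rng.normal(0.0, scale, size=(k * k * c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x):
        n, h, w, c = x.shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        s = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x, shape=(n, oh, ow, k, k, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
        )
        return cols.reshape(n * oh * ow, k * k * c), (n, oh, ow, c)

    def forward(self, x, train):
        cols, (n, oh, ow, _) = self._im2col(np.ascontiguousarray(x))
        if train:
            self._cols, self._xshape = cols, x.shape
        out = cols @ self.W + self.b
        return out.reshape(n, oh, ow, -1)

    def backward(self, grad):
        n, oh, ow, c_out = grad.shape
        g = grad.reshape(n * oh * ow, c_out)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, oh, ow, self.k, self.k, self.c_in)
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx


class MaxPool2D(Layer):
    def __init__(self, f: int = 2):
        super().__init__()
        self.f = f

    def forward(self, x, train):
        n, h, w, c = x.shape
        f = self.f
        blocks = x[:, : h // f * f, : w // f * f, :].reshape(n, h // f, f, w // f, f, c)
        out = blocks.max(axis=(2, 4))
        if train:
            self._mask = blocks == out[:, :, None, :, None, :]
            self._shape = x.shape
        return out

    def backward(self, grad):
        f = self.f
        g = self._mask * grad[:, :, None, :, None, :]
        n, hh, _, ww, _, c = g.shape
        dx = np.zeros(self._shape, dtype=np.float32)
        dx[:, : hh * f, : ww * f, :] = g.reshape(n, hh * f, ww * f, c)
        return dx


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain sequential network with softmax class output."""

    def __init__(self, layers: list[Layer], n_classes: int):
        self.layers = layers
        self.n_classes = n_classes
        self.trained = False
        #: Affine input standardisation (set from training data); identity until fit.
        self.input_mean: np.ndarray | None = None
        self.input_scale: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return int(sum(p.size for layer in self.layers for p in layer.params))

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if self.input_mean is not None:
            x = (x - self.input_mean) / self.input_scale
        return x

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self._standardize(x)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, chunk: int = 4096) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [softmax(self.logits(x[i:i + chunk])) for i in range(0, len(x), chunk)]
        return np.concatenate(outs) if outs else np.empty((0, self.n_classes))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    def l1_weight_norm(self) -> float:
        return float(sum(np.abs(l.params[0]).sum() for l in self.layers if l.l1_penalized))

    # -- persistence ------------------------------------------------------

    def save_weights(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_p{j}"] = p
        if self.input_mean is not None:
            arrays["input_mean"] = self.input_mean
            arrays["input_scale"] = self.input_scale
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        data = np.load(path)
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = data[f"layer{i}_p{j}"]
        if "input_mean" in data:
            self.input_mean = data["input_mean"]
            self.input_scale = data["input_scale"]
        self.trained = True


class Adam:
    """Adaptive-moment optimizer over all trainable layer parameters."""

    def __init__(self, layers: list[Layer], config: TrainConfig):
        self.cfg = config
        self.slots = [
            (layer, p, g, np.zeros_like(p), np.zeros_like(p))
            for layer in layers
            for p, g in zip(layer.params, layer.grads)
        ]
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        bias1 = 1.0 - c.beta1 ** self.t
        bias2 = 1.0 - c.beta2 ** self.t
        for layer, p, g, m, v in self.slots:
            if c.l1_lambda and layer.l1_penalized and p.ndim > 1:
                g = g + c.l1_lambda * np.sign(p)
            m *= c.beta1
            m += (1.0 - c.beta1) * g
            v *= c.beta2
            v += (1.0 - c.beta2) * g * g
            p -= c.lr * (m / bias1) / (np.sqrt(v / bias2) + c.eps)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def one_hot(y: np.ndarray, n_classes: int, smoothing: float = 0.0) -> np.ndarray:
    y = np.asarray(y, dtype=np.int64)
    out = np.full((len(y), n_classes), smoothing / n_classes, dtype=np.float32)
    out[np.arange(len(y)), y] += 1.0 - smoothing
    return out


def _eval(net: Network, x: np.ndarray, y: np.ndarray, smoothing: float) -> tuple[float, float]:
    """(accuracy %, cross-entropy loss) on a held-out set."""
    proba = net.predict_proba(x)
    acc = 100.0 * float(np.mean(np.argmax(proba, axis=1) == y))
    targets = one_hot(y, net.n_classes, smoothing)
    loss = float(-(targets * np.log(np.clip(proba, 1e-12, None))).sum(axis=1).mean())
    return acc, loss


def train_network(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    standardize: bool = True,
):
    """Train ``net`` with softmax cross-entropy (+ L1 on dense weights) and Adam.

    A ``val_fraction`` slice of the data is held out for per-epoch validation
    metrics.  Returns the per-epoch metric series (accuracy in percent, loss)
    from :mod:`hivesense.metrics`.
    """
    from .metrics import EpochMetrics

    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if len(X) == 0:
        raise InputError("empty training dataset")
    if len(X) != len(y):
        raise ShapeError("X and y lengths differ")
    if len(np.unique(y)) < 2:
        import logging

        logging.getLogger(__name__).warning(
            "training labels are degenerate (single class); accuracy will be trivial"
        )
    rng = np.random.default_rng(config.seed)
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-6] = 1.0
        net.input_mean, net.input_scale = mean.astype(np.float32), scale.astype(np.float32)

    n_val = int(round(config.val_fraction * len(X)))
    perm = rng.permutation(len(X))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0 or len(val_idx) == 0:  # degenerate tiny datasets
        tr_idx = val_idx = perm
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = Adam(net.layers, config)
    smoothing = config.label_smoothing
    epochs_acc, epochs_loss = [], []
    n = len(Xtr)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Xtr[idx]
            logits = net.logits(xb, train=True)
            proba = softmax(logits)
            targets = one_hot(ytr[idx], net.n_classes, smoothing)
            grad = (proba - targets) / len(idx)
            for layer in reversed(net.layers):
                grad = layer.backward(grad)
            opt.step()
        acc, loss = _eval(net, Xval, yval, smoothing)
        epochs_acc.append(acc)
        epochs_loss.append(loss)
    net.trained = True
    return EpochMetrics(
        accuracy=np.array(epochs_acc), loss=np.array(epochs_loss),
        epochs=np.arange(1, config.epochs + 1),
    )
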
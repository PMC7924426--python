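"""A small 20-layer deep convolutional network, implemented in numpy.

Architecture: one image input layer, then four blocks of
(convolution -> batch normalization -> ReLU -> 2x2 max pooling), then one
fully connected layer, a softmax layer, and a classification output layer
— 20 layers in total.  Defaults use 3x3 kernels with a doubling filter
schedule (8, 16, 32, 64), which reduces a 224 x 224 single-channel input
to a 14 x 14 x 64 tensor ahead of the dense layer.

Training is plain SGD with momentum on the cross-entropy loss.  The
implementation is deliberately self-contained (im2col convolutions via
stride tricks, float32 arithmetic) and fully deterministic under a fixed
seed, which the tests rely on.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EPS = 1e-5


class DcnnError(Exception):
    pass


@dataclass(frozen=True)
class DcnnConfig:
    input_size: int = 224
    n_classes: int = 4
    filters: tuple[int, ...] = (8, 16, 32, 64)
    kernel: int = 3
    pool: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filters) != 4:
            raise DcnnError("the network has exactly 4 convolution blocks")
        if self.kernel % 2 != 1:
            raise DcnnError("kernel size must be odd (same-padding convolutions)")
        if self.input_size % self.pool ** len(self.filters) != 0:
            raise DcnnError(
                f"input_size {self.input_size} must be divisible by "
                f"{self.pool ** len(self.filters)} for the pooling cascade"
            )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0


class _Conv:
    """Same-padding stride-1 convolution, weights (F, C, k, k)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.grads: dict[str, np.ndarray] = {}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        wm = self.W.transpose(1, 2, 3, 0).reshape(-1, self.W.shape[0])
        out = cols @ wm + self.b
        if train:
            self._cols, self._shape = cols, x.shape
        return np.ascontiguousarray(out.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        _, c, _, _ = self._shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        dwm = self._cols.T @ dmat
        self.grads["W"] = dwm.reshape(c, self.k, self.k, f).transpose(3, 0, 1, 2)
        self.grads["b"] = dmat.sum(axis=0)
        # dx = same-padding convolution of dout with the flipped kernels
        p = self.k // 2
        dpad = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(dpad, (self.k, self.k), axis=(2, 3))
        cols2 = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, f * self.k * self.k)
        wrot = np.flip(self.W, axis=(2, 3)).transpose(0, 2, 3, 1).reshape(-1, c)
        dx = (cols2 @ wrot).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(dx)


class _BatchNorm:
    def __init__(self, channels: int):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = 0.1
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu[None, :, None, None]) * ivstd[None, :, None, None]
        if train:
            self._cache = (xhat, ivstd)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivstd = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) * ivstd[None, :, None, None]
        self._cache = None
        return dx.astype(np.float32)


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class _MaxPool:
    def __init__(self, p: int):
        self.p = p
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.p
        xr = x.reshape(n, c, h // p, p, w // p, p)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            counts = mask.sum(axis=(3, 5), keepdims=True)
            self._cache = (mask, counts, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, counts, shape = self._cache
        p = self.p
        d = dout[:, :, :, None, :, None] / counts
        dx = (mask * d).reshape(shape)
        self._cache = None
        return dx.astype(np.float32)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.grads: dict[str, np.ndarray] = {}
        self._x = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n = x.shape[0]
        flat = x.reshape(n, -1)
        if train:
            self._x = (flat, x.shape)
        return flat @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        flat, shape = self._x
        self.grads["W"] = flat.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = (dout @ self.W.T).reshape(shape)
        self._x = None
        return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Dcnn:
    """Handle to the 20-layer network; built by :func:`build_dcnn`."""

    def __init__(self, cfg: DcnnConfig):
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.blocks = []
        c_in = 1
        for f in cfg.filters:
            self.blocks.append(
                {
                    "conv": _Conv(c_in, f, cfg.kernel, rng),
                    "bn": _BatchNorm(f),
                    "relu": _ReLU(),
                    "pool": _MaxPool(cfg.pool),
                }
            )
            c_in = f
        final_side = cfg.input_size // cfg.pool ** len(cfg.filters)
        self.dense = _Dense(final_side * final_side * cfg.filters[-1], cfg.n_classes, rng)
        self.trained = False

    @property
    def layer_names(self) -> list[str]:
        names = ["image_input"]
        for i in range(len(self.blocks)):
            names += [f"conv_{i+1}", f"batchnorm_{i+1}", f"relu_{i+1}", f"maxpool_{i+1}"]
        names += ["fully_connected", "softmax", "classification_output"]
        return names

    def _param_layers(self):
        for blk in self.blocks:
            yield blk["conv"]
            yield blk["bn"]
        yield self.dense

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (N, 1, S, S) float32 batch."""
        for blk in self.blocks:
            x = blk["conv"].forward(x, train)
            x = blk["bn"].forward(x, train)
            x = blk["relu"].forward(x, train)
            x = blk["pool"].forward(x, train)
        return self.dense.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense.backward(dlogits)
        for blk in reversed(self.blocks):
            d = blk["pool"].backward(d)
            d = blk["relu"].backward(d)
            d = blk["bn"].backward(d)
            d = blk["conv"].backward(d)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "Dcnn":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise DcnnError(f"{path} does not contain a Dcnn model")
        return model


def build_dcnn(cfg: DcnnConfig | None = None) -> Dcnn:
    """Build the 20-layer network with deterministic initialization."""
    return Dcnn(cfg or DcnnConfig())


def _to_batch(images: Sequence, size: int) -> np.ndarray:
    arrs = []
    for img in images:
        px = getattr(img, "pixels", img)
        px = np.asarray(px, dtype=np.float32)
        if px.shape != (size, size):
            raise DcnnError(f"expected {size}x{size} images, got {px.shape}")
        arrs.append(px / 255.0)
    return np.stack(arrs)[:, None, :, :]


def train(
    model: Dcnn,
    images: Sequence,
    labels: Sequence[int],
    cfg: TrainConfig = TrainConfig(),
) -> list[dict[str, float]]:
    """SGD-with-momentum training on cross-entropy; returns the epoch log.

    ``images`` are 8-bit arrays (or RepresentativeImage); they are scaled
    to [0, 1] internally.  Zero epochs leaves the model untouched.
    Deterministic for a fixed (model seed, train seed, data order).
    """
    y = np.asarray([int(l) for l in labels])
    if len(np.unique(y)) < 2:
        raise DcnnError("training requires at least 2 classes")
    if np.any(y < 0) or np.any(y >= model.config.n_classes):
        raise DcnnError("labels outside the configured class range")
    x = _to_batch(images, model.config.input_size)
    if len(x) != len(y):
        raise DcnnError("images and labels must have equal length")

    rng = np.random.default_rng(cfg.seed)
    velocity: dict[int, dict[str, np.ndarray]] = {}
    log: list[dict[str, float]] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        correct = 0
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            probs = _softmax(logits)
            losses.append(float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))))
            correct += int((probs.argmax(axis=1) == yb).sum())
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            model.backward((probs - onehot).astype(np.float32) / len(yb))
            for li, layer in enumerate(model._param_layers()):
                vel = velocity.setdefault(li, {})
                for name, p in layer.params().items():
                    g = layer.grads[name].astype(np.float32)
                    v = vel.get(name)
                    v = cfg.momentum * v - cfg.learning_rate * g if v is not None else -cfg.learning_rate * g
                    vel[name] = v
                    p += v
        log.append(
            {"epoch": epoch + 1, "loss": float(np.mean(losses)), "accuracy": correct / len(x)}
        )
        model.trained = True
    return log


def predict(model: Dcnn, images: Sequence, batch_size: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax probability vectors (rows sum to 1)."""
    x = _to_batch(images, model.config.input_size)
    probs = []
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start : start + batch_size], train=False)
        probs.append(_softmax(logits.astype(np.float64)))
    p = np.concatenate(probs)
    return p.argmax(axis=1), p


def confidence_percent(probs: np.ndarray) -> np.ndarray:
    """Reported classification confidence: max probability x 100%."""
    return 100.0 * np.max(probs, axis=1)
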
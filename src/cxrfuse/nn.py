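"""Minimal CNN training backend.

Implements the tiny image classifiers everything else in the package
manipulates: a stack of 3x3 conv blocks truncated at the deepest pooling
layer, a global-average-pooling (GAP) layer, and a dense two-unit head
whose softmax output is the probability of each class.  Weights of a model
are exposed as a :class:`WeightCollection` — the ordered, named set of
parameter tensors that the re-initialization strategies and the
weight-level ensembles operate on.

The engine is deliberately small: conv via im2col, ReLU, 2x2 max pooling,
GAP, dense, softmax cross-entropy, and Adam.  Everything is float64 numpy
and deterministic under an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "WeightCollection",
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "SmallConvNet",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


# ---------------------------------------------------------------------------
# Weight container


@dataclass(frozen=True)
class WeightCollection:
    """Ordered, named parameter tensors of one model.

    Two collections are mergeable iff their *fingerprints* — the ordered
    (name, shape) pairs — are identical.
    """

    items: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "items", tuple((n, np.asarray(t, dtype=float)) for n, t in self.items)
        )

    @property
    def fingerprint(self) -> tuple[tuple[str, tuple[int, ...]], ...]:
        return tuple((name, tensor.shape) for name, tensor in self.items)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.items)

    def get(self, name: str) -> np.ndarray:
        for n, t in self.items:
            if n == name:
                return t
        raise KeyError(name)

    def flatten(self) -> np.ndarray:
        """All parameter values as one 1-D vector (layer order preserved)."""
        if not self.items:
            raise ValueError("empty weight collection")
        return np.concatenate([t.ravel() for _, t in self.items])

    def map(self, fn: Callable[[str, np.ndarray], np.ndarray]) -> "WeightCollection":
        return WeightCollection(tuple((n, fn(n, t)) for n, t in self.items))

    def copy(self) -> "WeightCollection":
        return WeightCollection(tuple((n, t.copy()) for n, t in self.items))

    def allclose(self, other: "WeightCollection", atol: float = 0.0) -> bool:
        if self.fingerprint != other.fingerprint:
            return False
        return all(
            np.allclose(a, b, atol=atol, rtol=0.0)
            for (_, a), (_, b) in zip(self.items, other.items)
        )

    def content_hash(self) -> int:
        """Hash of the exact parameter bytes (used to assert freezing)."""
        h = 0
        for name, t in self.items:
            h ^= hash((name, t.tobytes()))
        return h


# ---------------------------------------------------------------------------
# Layers


class Layer:
    """Base layer: forward caches what backward needs; params are dicts."""

    name: str = ""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patches for stride-1 'same' conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # sliding windows over the two spatial axes
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k) -> (N, H*W, C*k*k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


class Conv2D(Layer):
    """3x3 stride-1 'same' convolution followed by nothing (linear)."""

    def __init__(self, c_in: int, c_out: int, name: str, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.name = name
        self.W = np.zeros((c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.c_in * self.k * self.k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=self.W.shape)
        self.b = np.zeros(self.c_out)

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        pad = self.k // 2
        cols = _im2col(x, self.k, pad)  # (N, H*W, C*k*k)
        wmat = self.W.reshape(self.c_out, -1)  # (C_out, C*k*k)
        out = cols @ wmat.T + self.b  # (N, H*W, C_out)
        self._cols, self._shape = cols, (n, c, h, w)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = grad.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (N,HW,C_out)
        wmat = self.W.reshape(self.c_out, -1)
        self.dW = np.einsum("npo,npk->ok", g, self._cols).reshape(self.W.shape)
        self.db = g.sum(axis=(0, 1))
        dcols = g @ wmat  # (N, HW, C*k*k)
        # col2im: scatter-add patches back
        pad = self.k // 2
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        dcols = dcols.reshape(n, h, w, c, self.k, self.k)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, pad : pad + h, pad : pad + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 stride-2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = (n, c, h, w)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = grad[:, :, :, None, :, None] * self._mask
        return g.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """Spatial mean of each feature map: (N,C,H,W) -> (N,C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, name: str):
        self.d_in, self.d_out = d_in, d_out
        self.name = name
        self.W = np.zeros((d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init(self, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / self.d_in), size=self.W.shape)
        self.b = np.zeros(self.d_out)

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


# ---------------------------------------------------------------------------
# Loss


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


# ---------------------------------------------------------------------------
# Model


class SmallConvNet:
    """Conv blocks -> deepest pooling -> GAP -> dense(2) -> softmax.

    ``channels`` gives the output width of each conv block; every block is
    conv3x3 + ReLU + maxpool2x2, so an input of size S needs S divisible by
    2**len(channels).
    """

    def __init__(self, image_size: int, channels: Sequence[int] = (8, 16, 32)):
        if image_size % (2 ** len(channels)) != 0:
            raise ValueError(
                f"image size {image_size} not divisible by 2^{len(channels)}; "
                "shrink the conv stack or enlarge the image"
            )
        self.image_size = int(image_size)
        self.channels = tuple(int(c) for c in channels)
        self.layers: list[Layer] = []
        c_prev = 1
        for i, c in enumerate(self.channels):
            self.layers += [Conv2D(c_prev, c, name=f"conv{i + 1}"), ReLU(), MaxPool2D()]
            c_prev = c
        self.gap = GlobalAvgPool()
        self.head = Dense(c_prev, 2, name="head")
        self.layers += [self.gap, self.head]

    @property
    def feature_width(self) -> int:
        """Width of the GAP feature vector (last conv-block channel count)."""
        return self.channels[-1]

    def init_weights(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            if isinstance(layer, (Conv2D, Dense)):
                layer.init(rng)

    # -- weight (de)serialization ------------------------------------------
    def get_weights(self) -> WeightCollection:
        items: list[tuple[str, np.ndarray]] = []
        for layer in self.layers:
            for name, t in layer.params().items():
                items.append((name, t.copy()))
        return WeightCollection(tuple(items))

    def set_weights(self, weights: WeightCollection) -> None:
        own = self.get_weights().fingerprint
        if weights.fingerprint != own:
            for (na, sa), (nb, sb) in zip(own, weights.fingerprint):
                if (na, sa) != (nb, sb):
                    raise ValueError(
                        f"weight mismatch at layer {na!r}: model expects {sa}, got {nb!r} {sb}"
                    )
            raise ValueError("weight collection does not match model architecture")
        lookup = dict(weights.items)
        for layer in self.layers:
            for name in layer.params():
                setattr(layer, name.split(".")[-1], lookup[name].copy())

    # -- forward / backward -------------------------------------------------
    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:  # (N, H, W) single channel
            x = x[:, None, :, :]
        return x - 0.5  # inputs live in [0,1]; center for conditioning

    def logits(self, x: np.ndarray) -> np.ndarray:
        out = self._as_batch(x)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def features(self, x: np.ndarray) -> np.ndarray:
        """GAP feature vectors (the head's input), shape (N, feature_width)."""
        out = self._as_batch(x)
        for layer in self.layers[:-1]:  # stop before the dense head
            out = layer.forward(out)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x), axis=1)

    def predict_scores(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Probability of the positive (abnormal) class per sample."""
        x = np.asarray(x, dtype=float)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.predict_proba(x[i : i + batch_size])[:, 1])
        return np.concatenate(out)

    def loss_on(self, x: np.ndarray, labels: np.ndarray, batch_size: int = 256) -> float:
        """Mean cross-entropy on a dataset (no parameter updates)."""
        x = np.asarray(x, dtype=float)
        labels = np.asarray(labels)
        total, n = 0.0, x.shape[0]
        for i in range(0, n, batch_size):
            xb, yb = x[i : i + batch_size], labels[i : i + batch_size]
            loss, _ = softmax_cross_entropy(self.logits(xb), yb)
            total += loss * xb.shape[0]
        return total / n

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            out.update(layer.params())
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            out.update(layer.grads())
        return out

    def apply_param_update(self, new_values: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for name in layer.params():
                setattr(layer, name.split(".")[-1], new_values[name])


# ---------------------------------------------------------------------------
# Optimizer


@dataclass
class Adam:
    """Adam with the usual defaults; state keyed by parameter name."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict[str, np.ndarray] = field(default_factory=dict)
    _v: dict[str, np.ndarray] = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        self._t += 1
        out: dict[str, np.ndarray] = {}
        for name, p in params.items():
            g = grads[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m[:] = self.beta1 * m + (1 - self.beta1) * g
            v[:] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self._t)
            vhat = v / (1 - self.beta2**self._t)
            out[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out
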
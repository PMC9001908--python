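"""A small deterministic CNN engine on NumPy.

Provides exactly the pieces the segmentation network needs: 2-D convolution
(kernel 1 or 3, stride 1, 'same' padding) via im2col, instance normalisation,
ReLU, 2x2 max-pooling that records its argmax indices, the matching
max-unpooling, residual blocks, and an Adam optimiser.  Forward and backward
passes are plain ``float32`` NumPy, so training and inference are bit-for-bit
reproducible for a fixed seed on a fixed platform — no framework
nondeterminism to work around.

Tensors are ``(N, C, H, W)``.  Each layer caches what its backward pass needs
during ``forward`` and releases it after ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "InstanceNorm",
    "ReLU",
    "MaxPool2x2",
    "max_unpool_2x2",
    "max_unpool_2x2_backward",
    "BasicBlock",
    "BottleneckBlock",
    "ConvBNRelu",
    "Adam",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """'Same' convolution with kernel size 1 or 3, stride 1, He-normal init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError(f"kernel size must be 1 or 3, got {k}")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std, size=(fan_in, cout)))
        self.bias = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, (self.k - 1) // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        self._cols, self._shape = cols, (n, c, h, w)
        y = cols @ self.weight.value + self.bias.value
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape  # type: ignore[misc]
        k, p = self.k, (self.k - 1) // 2
        gy_flat = gy.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.weight.grad += self._cols.T @ gy_flat  # type: ignore[union-attr]
        self.bias.grad += gy_flat.sum(axis=0)
        gcols = (gy_flat @ self.weight.value.T).reshape(n, h, w, c, k, k)
        self._cols = None
        if k == 1:
            return np.ascontiguousarray(gcols[..., 0, 0].transpose(0, 3, 1, 2))
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + h, j : j + w] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return gx[:, :, p : p + h, p : p + w]


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation over (H, W), with learned affine.

    Unlike batch statistics, instance statistics make inference independent of
    batch composition, so a saved model predicts identically in any batch.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache  # type: ignore[misc]
        self._cache = None
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = gy * self.gamma.value[None, :, None, None]
        m1 = g.mean(axis=(2, 3), keepdims=True)
        m2 = (g * xhat).mean(axis=(2, 3), keepdims=True)
        return inv_std * (g - m1 - xhat * m2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


class MaxPool2x2(Layer):
    """2x2 max pooling; stores argmax indices for SegNet-style unpooling."""

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, c, h, w = x.shape
        x4 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = x4.argmax(axis=-1)
        self._idx, self._inshape = idx, (n, c, h, w)
        pooled = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]
        return pooled, idx

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        g4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(g4, self._idx[..., None], gy[..., None], axis=-1)
        self._idx = None
        return g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


def max_unpool_2x2(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Scatter pooled values back to their argmax positions (others zero)."""
    n, c, h, w = x.shape
    out4 = np.zeros((n, c, h, w, 4), dtype=np.float32)
    np.put_along_axis(out4, idx[..., None], x[..., None], axis=-1)
    return out4.reshape(n, c, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, 2 * h, 2 * w
    )


def max_unpool_2x2_backward(gy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n, c, h2, w2 = gy.shape
    h, w = h2 // 2, w2 // 2
    g4 = gy.reshape(n, c, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w, 4)
    return np.take_along_axis(g4, idx[..., None], axis=-1)[..., 0]


class ConvBNRelu(Layer):
    """conv -> instance norm -> ReLU, the workhorse decoder/stem unit."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.conv = Conv2d(cin, cout, k, rng)
        self.norm = InstanceNorm(cout)
        self.act = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + self.norm.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.norm.backward(self.act.backward(gy)))


class BasicBlock(Layer):
    """Two 3x3 convolutions with an identity (or 1x1-projected) shortcut."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.norm1 = InstanceNorm(cout)
        self.act1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.norm2 = InstanceNorm(cout)
        self.act_out = ReLU()
        self.proj = None if cin == cout else Conv2d(cin, cout, 1, rng)

    def params(self) -> list[Param]:
        ps = (
            self.conv1.params()
            + self.norm1.params()
            + self.conv2.params()
            + self.norm2.params()
        )
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.act1.forward(self.norm1.forward(self.conv1.forward(x)))
        y = self.norm2.forward(self.conv2.forward(y))
        shortcut = x if self.proj is None else self.proj.forward(x)
        return self.act_out.forward(y + shortcut)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.act_out.backward(gy)
        g_main = self.norm2.backward(g)
        g_main = self.conv2.backward(g_main)
        g_main = self.conv1.backward(self.norm1.backward(self.act1.backward(g_main)))
        g_short = g if self.proj is None else self.proj.backward(g)
        return g_main + g_short


class BottleneckBlock(Layer):
    """1x1 reduce -> 3x3 -> 1x1 expand with shortcut (ResNet-50 style)."""

    def __init__(self, cin: int, cmid: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cmid, 1, rng)
        self.norm1 = InstanceNorm(cmid)
        self.act1 = ReLU()
        self.conv2 = Conv2d(cmid, cmid, 3, rng)
        self.norm2 = InstanceNorm(cmid)
        self.act2 = ReLU()
        self.conv3 = Conv2d(cmid, cout, 1, rng)
        self.norm3 = InstanceNorm(cout)
        self.act_out = ReLU()
        self.proj = None if cin == cout else Conv2d(cin, cout, 1, rng)

    def params(self) -> list[Param]:
        ps = (
            self.conv1.params()
            + self.norm1.params()
            + self.conv2.params()
            + self.norm2.params()
            + self.conv3.params()
            + self.norm3.params()
        )
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.act1.forward(self.norm1.forward(self.conv1.forward(x)))
        y = self.act2.forward(self.norm2.forward(self.conv2.forward(y)))
        y = self.norm3.forward(self.conv3.forward(y))
        shortcut = x if self.proj is None else self.proj.forward(x)
        return self.act_out.forward(y + shortcut)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.act_out.backward(gy)
        g_main = self.norm3.backward(g)
        g_main = self.conv3.backward(g_main)
        g_main = self.conv2.backward(self.norm2.backward(self.act2.backward(g_main)))
        g_main = self.conv1.backward(self.norm1.backward(self.act1.backward(g_main)))
        g_short = g if self.proj is None else self.proj.backward(g)
        return g_main + g_short


class Adam:
    """Adaptive-moment optimiser with the standard bias correction."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
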
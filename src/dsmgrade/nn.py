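"""Minimal NumPy neural-network engine (NCHW layout).

Layers cache what their backward pass needs during ``forward`` and accumulate
parameter gradients in-place during ``backward``; :class:`Adam` then steps the
parameters.  Only the pieces the grading network needs are implemented:
3×3/1×1 convolutions (im2col), batch normalization, ReLU/ReLU6/Sigmoid,
2×2 max pooling, global average pooling, linear maps and a squeeze-and-
excitation block whose squeeze is the midpoint of global average and global
max pooling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "SEBlock",
    "Sequential",
    "Adam",
    "relu6",
    "sigmoid",
    "softmax",
    "kaiming_uniform",
]


def relu6(x: np.ndarray) -> np.ndarray:
    """min(max(x, 0), 6)."""
    return np.clip(x, 0.0, 6.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-uniform initialization: U(−√(6/fan_in), √(6/fan_in))."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) → (N, H·W, C·k·k) patches for a stride-1 convolution."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + oh, j : j + ow]
    return cols.reshape(n, c * k * k, oh * ow).transpose(0, 2, 1)


def _col2im(dcols: np.ndarray, x_shape: tuple[int, ...], k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add back to image layout)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = hp - k + 1, wp - k + 1
    dcols = dcols.transpose(0, 2, 1).reshape(n, c, k, k, oh, ow)
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + oh, j : j + ow] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d(Layer):
    """Stride-1 k×k convolution with 'same' padding for k=3, none for k=1."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel * kernel
        self.weight = Param(kaiming_uniform(rng, (out_channels, fan_in), fan_in), "conv.weight")
        self.bias = Param(np.zeros(out_channels), "conv.bias") if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.kernel, self.pad)  # (N, HW, C·k²)
        out = cols @ self.weight.value.T  # (N, HW, Cout)
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, self.out_channels, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, co, h, w = dout.shape
        dflat = dout.reshape(n, co, h * w).transpose(0, 2, 1)  # (N, HW, Cout)
        self.weight.grad += np.einsum("npo,npk->ok", dflat, cols)
        if self.bias is not None:
            self.bias.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ self.weight.value  # (N, HW, C·k²)
        return _col2im(dcols, x_shape, self.kernel, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with EMA running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            if x.shape[0] < 2:
                raise ValueError("batch normalization needs a batch of at least 2 in train mode")
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))  # biased, 1/m
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        # standard train-mode BN gradient
        sum_d = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * dxhat - sum_d - xhat * sum_dx)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """2×2 max pooling with stride 2 (even spatial sizes only)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}×{w} not divisible by the 2×2 pool")
        tiles = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        tiles = tiles.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = tiles.argmax(axis=-1)
        self._x_shape = x.shape
        return tiles.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, oh, ow = dout.shape
        flat = np.zeros((n, c, oh, ow, 4), dtype=dout.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dout[..., None], axis=-1)
        flat = flat.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(self._x_shape)


class GlobalAvgPool(Layer):
    """(N, C, H, W) → (N, C) spatial mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        return np.broadcast_to(dout[:, :, None, None], self._x_shape) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._x_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.weight = Param(kaiming_uniform(rng, (out_features, in_features), in_features), "linear.weight")
        self.bias = Param(np.zeros(out_features), "linear.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


class SEBlock(Layer):
    """Channel attention: squeeze = (GAP + GMP)/2, excite = σ∘L2∘ReLU6∘L1.

    The squeeze midpoint of global average and global max pooling counters the
    uneven weight distribution plain averaging produces; the excitation output
    lies strictly in (0, 1) and rescales each channel of the input.
    """

    def __init__(self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None) -> None:
        if channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.channels = channels
        self.w1 = Param(kaiming_uniform(rng, (hidden, channels), channels), "se.w1")
        self.b1 = Param(np.zeros(hidden), "se.b1")
        self.w2 = Param(kaiming_uniform(rng, (channels, hidden), hidden), "se.w2")
        self.b2 = Param(np.zeros(channels), "se.b2")

    def params(self) -> list[Param]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._argmax = flat.argmax(axis=-1)
        z = (flat.mean(axis=-1) + flat.max(axis=-1)) / 2.0
        a1 = z @ self.w1.value.T + self.b1.value
        h1 = relu6(a1)
        a2 = h1 @ self.w2.value.T + self.b2.value
        s = sigmoid(a2)
        self._cache = (x, z, a1, h1, s)
        return x * s[:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, z, a1, h1, s = self._cache
        n, c, h, w = x.shape
        ds = (dout * x).sum(axis=(2, 3))
        dx = dout * s[:, :, None, None]
        da2 = ds * s * (1.0 - s)
        self.w2.grad += da2.T @ h1
        self.b2.grad += da2.sum(axis=0)
        dh1 = da2 @ self.w2.value
        da1 = dh1 * ((a1 > 0) & (a1 < 6))
        self.w1.grad += da1.T @ z
        self.b1.grad += da1.sum(axis=0)
        dz = da1 @ self.w1.value
        # z = (mean + max)/2 — half the gradient spreads uniformly, half goes
        # to each channel's argmax position
        dx += dz[:, :, None, None] / (2.0 * h * w)
        dmax = np.zeros((n, c, h * w))
        np.put_along_axis(dmax, self._argmax[..., None], (dz / 2.0)[..., None], axis=-1)
        dx += dmax.reshape(n, c, h, w)
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimizer (β1=0.9, β2=0.999) with bias correction."""

    def __init__(self, params: list[Param], lr: float = 2e-4, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            mhat = m / (1.0 - self.b1**self.t)
            vhat = v / (1.0 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
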
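"""Compact CPU engine for small volumetric convolutional networks.

Implements exactly the operators a 3D DenseNet regression head needs —
3D convolution (im2col + GEMM), batch normalization, ReLU, average/max
pooling, global average pooling, a linear head, dense blocks with feature
concatenation, mean-squared-error loss and the Adam optimizer — with manual
backpropagation. Arrays are ``(N, C, D, H, W)``; float32 by default, float64
available for numerical gradient checking.

All parameter initialization draws from an explicit ``numpy`` Generator so a
seed fully determines the network.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "AvgPool3d",
    "MaxPool3d",
    "GlobalAvgPool3d",
    "Flatten",
    "Linear",
    "Sequential",
    "DenseLayer",
    "DenseBlock",
    "Transition",
    "Adam",
    "mse_loss",
    "parameter_checksum",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Layer):
    """3D convolution with isotropic kernel/stride and zero padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = False,
        dtype=np.float32,
    ) -> None:
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel**3
        self.w = Param(_he_normal(rng, (out_ch, fan_in), fan_in, dtype), "conv.w")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "conv.b") if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]  # (N, C, Do, Ho, Wo, k, k, k)
        n, c, do, ho, wo = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * k**3)
        return np.ascontiguousarray(cols), (n, do, ho, wo)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        cols, (n, do, ho, wo) = self._im2col(xp)
        out = cols @ self.w.value.T
        if self.b is not None:
            out += self.b.value
        self._cache = (cols, xp.shape, x.shape, (n, do, ho, wo)) if train else None
        return out.reshape(n, do, ho, wo, self.out_ch).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, x_shape, (n, do, ho, wo) = self._cache
        dmat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_ch)
        self.w.grad += (dmat.T @ cols).astype(self.w.value.dtype)
        if self.b is not None:
            self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.w.value).reshape(n, do, ho, wo, self.in_ch, self.k, self.k, self.k)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        s = self.stride
        # scatter-add one kernel offset at a time (k^3 vectorized adds)
        for dz in range(self.k):
            for dy in range(self.k):
                for dx in range(self.k):
                    dxp[
                        :, :,
                        dz : dz + s * do : s,
                        dy : dy + s * ho : s,
                        dx : dx + s * wo : s,
                    ] += dcols[:, :, :, :, :, dz, dy, dx].transpose(0, 4, 1, 2, 3)
        p = self.pad
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        assert dxp.shape == x_shape
        return dxp


class BatchNorm3d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32) -> None:
        self.gamma = Param(np.ones(ch, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(ch, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, x_shape = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shape)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv.reshape(shape)
        return dx.astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool3d(Layer):
    """Non-overlapping 2x2x2 average pooling (trailing odd voxels dropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        self._in_shape = x.shape
        xt = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        return xt.reshape(n, c, d2, 2, h2, 2, w2, 2).mean(axis=(3, 5, 7))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        up = np.repeat(np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
        dx[:, :, : up.shape[2], : up.shape[3], : up.shape[4]] = up
        return dx


class MaxPool3d(Layer):
    """Non-overlapping 2x2x2 max pooling (trailing odd voxels dropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        self._in_shape = x.shape
        xt = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        win = xt.reshape(n, c, d2, 2, h2, 2, w2, 2)
        out = win.max(axis=(3, 5, 7))
        if train:
            self._argmask = win == out[:, :, :, None, :, None, :, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        mask = self._argmask
        # split ties evenly so the gradient stays exact
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        spread = mask * (dout[:, :, :, None, :, None, :, None] / counts)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : 2 * d2, : 2 * h2, : 2 * w2] = spread.reshape(n, c, 2 * d2, 2 * h2, 2 * w2)
        return dx


class GlobalAvgPool3d(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None, None], self._in_shape) / (d * h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32) -> None:
        self.w = Param(_he_normal(rng, (n_out, n_in), n_in, dtype), "linear.w")
        self.b = Param(np.zeros(n_out, dtype=dtype), "linear.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class DenseLayer(Layer):
    """BN-ReLU-(1x1 bottleneck)-BN-ReLU-3x3 conv producing ``growth`` features.

    The caller concatenates the output onto the running feature stack.
    """

    def __init__(
        self,
        in_ch: int,
        growth: int,
        rng: np.random.Generator,
        bottleneck: bool = True,
        bn_size: int = 4,
        dtype=np.float32,
    ) -> None:
        inner: list[Layer] = [BatchNorm3d(in_ch, dtype=dtype), ReLU()]
        ch = in_ch
        if bottleneck:
            inner.append(Conv3d(ch, bn_size * growth, 1, rng, dtype=dtype))
            ch = bn_size * growth
            inner += [BatchNorm3d(ch, dtype=dtype), ReLU()]
        inner.append(Conv3d(ch, growth, 3, rng, dtype=dtype))
        self.net = Sequential(inner)

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


class DenseBlock(Layer):
    """A stack of dense layers with feature concatenation."""

    def __init__(
        self,
        in_ch: int,
        n_layers: int,
        growth: int,
        rng: np.random.Generator,
        bottleneck: bool = True,
        bn_size: int = 4,
        dtype=np.float32,
    ) -> None:
        self.layers = [
            DenseLayer(in_ch + i * growth, growth, rng, bottleneck, bn_size, dtype)
            for i in range(n_layers)
        ]
        self.growth = growth
        self.out_ch = in_ch + n_layers * growth

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        feats = x
        for l in self.layers:
            new = l.forward(feats, train)
            feats = np.concatenate([feats, new], axis=1)
        return feats

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = self.growth
        dfeats = dout
        for l in reversed(self.layers):
            dprev, dnew = dfeats[:, :-g], dfeats[:, -g:]
            dfeats = dprev + l.backward(np.ascontiguousarray(dnew))
        return dfeats


class Transition(Layer):
    """BN-ReLU-1x1 conv (channel compression) followed by 2x average pooling."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=np.float32) -> None:
        self.net = Sequential(
            [BatchNorm3d(in_ch, dtype=dtype), ReLU(), Conv3d(in_ch, out_ch, 1, rng, dtype=dtype), AvgPool3d()]
        )
        self.out_ch = out_ch

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries; returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff.astype(pred.dtype)


class Adam:
    """Adam with bias correction; one (m, v) slot pair per parameter."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.value.dtype)


def parameter_checksum(params: Sequence[Param]) -> str:
    """Stable hex digest of all parameter values, for determinism checks."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value, dtype=np.float64).tobytes())
    return h.hexdigest()
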
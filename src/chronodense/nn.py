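"""Minimal numpy layers with explicit forward/backward passes.

Each layer caches what its backward pass needs, accumulates parameter
gradients in-place, and returns the gradient with respect to its input.
Only the pieces the dense dilated-causal architecture needs are provided:
1-D convolution, ReLU, max/average/global-average pooling and an affine map.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .conv import ConvSpec, _padding


class Layer:
    """Base class; layers without parameters inherit the empty containers."""

    def parameters(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(())

    def gradients(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(())

    def zero_grad(self) -> None:
        for _, g in self.gradients():
            g[...] = 0.0


class Conv1d(Layer):
    """1-D convolution over ``[N, C, T]`` batches, causal or symmetric padding.

    Weights are He-normal initialised (fan-in = ``C_in * k``), biases zero.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int = 1,
        stride: int = 1,
        causal: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.spec = ConvSpec(in_channels, out_channels, kernel_size, dilation, stride, causal)
        rng = rng if rng is not None else np.random.default_rng(0)
        std = math.sqrt(2.0 / (in_channels * kernel_size))
        self.weight = rng.normal(0.0, std, (out_channels, in_channels, kernel_size))
        self.bias = np.zeros(out_channels)
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)
        self._cache: tuple | None = None

    def parameters(self):
        yield "weight", self.weight
        yield "bias", self.bias

    def gradients(self):
        yield "weight", self.gweight
        yield "bias", self.gbias

    def forward(self, x: np.ndarray) -> np.ndarray:
        spec = self.spec
        n, c, t = x.shape
        if c != spec.in_channels:
            raise ValueError(f"input has {c} channels, layer expects {spec.in_channels}")
        left, right = _padding(spec)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        t_out = spec.out_length(t)
        d, s = spec.dilation, spec.stride
        stop = (t_out - 1) * s + 1
        out = np.empty((n, spec.out_channels, t_out))
        out[:] = self.bias[None, :, None]
        for j in range(spec.kernel_size):
            seg = xp[:, :, j * d : j * d + stop : s]
            out += np.einsum("oi,nit->not", self.weight[:, :, j], seg, optimize=True)
        self._cache = (xp, t, t_out, left, right)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp, t, t_out, left, right = self._cache
        spec = self.spec
        d, s = spec.dilation, spec.stride
        stop = (t_out - 1) * s + 1
        gxp = np.zeros_like(xp)
        for j in range(spec.kernel_size):
            sl = slice(j * d, j * d + stop, s)
            seg = xp[:, :, sl]
            self.gweight[:, :, j] += np.einsum("not,nit->oi", gout, seg, optimize=True)
            gxp[:, :, sl] += np.einsum("oi,not->nit", self.weight[:, :, j], gout, optimize=True)
        self.gbias += gout.sum(axis=(0, 2))
        end = xp.shape[2] - right
        return gxp[:, :, left:end]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0)


class MaxPool1d(Layer):
    """Unpadded max pooling; input shorter than the window is an error."""

    def __init__(self, window: int = 3, stride: int = 2) -> None:
        self.window, self.stride = window, stride

    def out_length(self, t: int) -> int:
        if t < self.window:
            raise ValueError(
                f"sequence of length {t} is shorter than the pooling window {self.window}"
            )
        return (t - self.window) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, t = x.shape
        t_out = self.out_length(t)
        win = np.lib.stride_tricks.sliding_window_view(x, self.window, axis=2)
        win = win[:, :, :: self.stride][:, :, :t_out]
        idx = win.argmax(axis=3)
        self._cache = (x.shape, idx)
        return np.take_along_axis(win, idx[..., None], axis=3)[..., 0]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        shape, idx = self._cache
        gx = np.zeros(shape)
        n, c, t_out = gout.shape
        # absolute time index of each pooled maximum
        tpos = idx + self.stride * np.arange(t_out)[None, None, :]
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(gx, (ni, ci, tpos), gout)
        return gx


class AvgPool1d(Layer):
    """Unpadded average pooling (the transition blocks use window=stride=2)."""

    def __init__(self, window: int = 2, stride: int = 2) -> None:
        self.window, self.stride = window, stride

    def out_length(self, t: int) -> int:
        if t < self.window:
            raise ValueError(
                f"sequence of length {t} is shorter than the pooling window {self.window}"
            )
        return (t - self.window) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        t_out = self.out_length(x.shape[2])
        win = np.lib.stride_tricks.sliding_window_view(x, self.window, axis=2)
        win = win[:, :, :: self.stride][:, :, :t_out]
        self._in_shape = x.shape
        return win.mean(axis=3)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._in_shape)
        t_out = gout.shape[2]
        share = gout / self.window
        for j in range(self.window):
            gx[:, :, j : j + (t_out - 1) * self.stride + 1 : self.stride] += share
        return gx


class GlobalAvgPool(Layer):
    """Collapse the time axis to a single feature vector per channel."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.repeat(gout[:, :, None], self._t, axis=2) / self._t


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        std = 1.0 / math.sqrt(in_features)
        self.weight = rng.normal(0.0, std, (out_features, in_features))
        self.bias = np.zeros(out_features)
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)

    def parameters(self):
        yield "weight", self.weight
        yield "bias", self.bias

    def gradients(self):
        yield "weight", self.gweight
        yield "bias", self.gbias

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gweight += gout.T @ self._x
        self.gbias += gout.sum(axis=0)
        return gout @ self.weight
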
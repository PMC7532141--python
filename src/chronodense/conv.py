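"""Causal dilated 1-D convolution primitives and receptive-field calculus.

The output of a *causal* convolution at time-step ``t`` depends only on input
samples at times ``<= t``; this is realised by left-padding the signal with
``(k - 1) * d`` zeros, which also preserves the sequence length at stride 1.
A *dilated* convolution with dilation ``d`` spaces its kernel taps ``d``
samples apart, so stacking layers with growing dilations widens the temporal
context geometrically without any pooling.

Arrays are channel-major ``[C, T]`` with a 0-based time index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConvSpec", "causal_conv1d", "conv1d_batch", "receptive_field"]


@dataclass(frozen=True)
class ConvSpec:
    """Shape/geometry record for one 1-D convolution layer.

    ``causal=True`` guarantees equal input/output length at ``stride=1`` and a
    strictly backward-looking dependency cone.
    """

    in_channels: int
    out_channels: int
    kernel_size: int
    dilation: int = 1
    stride: int = 1
    causal: bool = True

    def __post_init__(self) -> None:
        for name in ("in_channels", "out_channels", "kernel_size", "dilation", "stride"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"ConvSpec.{name} must be a positive integer, got {v!r}")

    @property
    def span(self) -> int:
        """Temporal extent of the kernel: ``(k - 1) * d + 1`` input samples."""
        return (self.kernel_size - 1) * self.dilation + 1

    def out_length(self, t: int) -> int:
        """Output length for an input of length ``t`` (padding included)."""
        if t < 1:
            raise ValueError(f"input length must be positive, got {t}")
        return (t - 1) // self.stride + 1


def _padding(spec: ConvSpec) -> tuple[int, int]:
    pad = (spec.kernel_size - 1) * spec.dilation
    if spec.causal:
        return pad, 0
    return pad // 2, pad - pad // 2


def conv1d_batch(
    x: np.ndarray, spec: ConvSpec, weights: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Batched convolution on ``[N, C_in, T]`` input; returns ``[N, C_out, T']``.

    Computed as a sum over kernel taps of strided slices against the per-tap
    weight matrix, which keeps memory at O(NCT) and vectorises over the batch.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected [N, C, T] input, got shape {x.shape}")
    n, c_in, t = x.shape
    if t < 1:
        raise ValueError("input length must be positive")
    if c_in != spec.in_channels:
        raise ValueError(f"input has {c_in} channels, spec expects {spec.in_channels}")
    weights = np.asarray(weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    expected = (spec.out_channels, spec.in_channels, spec.kernel_size)
    if weights.shape != expected:
        raise ValueError(f"weights shape {weights.shape} != spec shape {expected}")
    if bias.shape != (spec.out_channels,):
        raise ValueError(f"bias shape {bias.shape} != ({spec.out_channels},)")

    left, right = _padding(spec)
    xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
    t_out = spec.out_length(t)
    out = np.zeros((n, spec.out_channels, t_out), dtype=float)
    d, s = spec.dilation, spec.stride
    stop = (t_out - 1) * s + 1
    for j in range(spec.kernel_size):
        seg = xp[:, :, j * d : j * d + stop : s]
        out += np.einsum("oi,nit->not", weights[:, :, j], seg, optimize=True)
    out += bias[None, :, None]
    return out


def causal_conv1d(
    x: np.ndarray, spec: ConvSpec, weights: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Single-sample 1-D convolution: ``[C_in, T] -> [C_out, T']``.

    With ``spec.causal`` and ``stride=1`` the output length equals the input
    length and the value at index ``t`` depends only on ``x[:, :t + 1]``.
    Non-causal mode uses symmetric zero padding (same length at stride 1).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected [C, T] input, got shape {x.shape}")
    return conv1d_batch(x[None], spec, weights, bias)[0]


def receptive_field(layers: Sequence[ConvSpec]) -> int:
    """Number of input time-steps that can influence one output time-step.

    ``RF = 1 + sum_i (k_i - 1) * d_i * prod_{j<i} stride_j`` — each layer adds
    its dilated kernel span scaled by the cumulative downsampling before it.
    Pooling layers may be modelled as ConvSpecs with ``kernel_size=window``.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("receptive_field requires a non-empty layer sequence")
    rf = 1
    jump = 1
    for spec in layers:
        rf += (spec.kernel_size - 1) * spec.dilation * jump
        jump *= spec.stride
    return rf
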
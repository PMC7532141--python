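"""A deliberately small-context baseline classifier.

One undilated causal convolution (kernel 3), ReLU, global average pooling and
an affine head: its receptive field spans three input samples, so it can only
exploit short-scale structure.  It exposes the same interface as
:class:`~chronodense.model.Network`, so :func:`~chronodense.training.fit`
trains it unchanged.  Used to demonstrate that class structure living at long
temporal scales is invisible without dilation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv1d, GlobalAvgPool, Linear, ReLU


@dataclass(frozen=True)
class _HeadOnlyConfig:
    input_channels: int
    num_classes: int
    head: str


class ShallowConvBaseline:
    """Single causal conv (k=3, d=1) -> ReLU -> global average pool -> affine."""

    def __init__(
        self,
        input_channels: int,
        num_classes: int,
        width: int = 16,
        kernel_size: int = 3,
        dilation: int = 1,
        head: str = "multiclass-softmax",
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.config = _HeadOnlyConfig(input_channels, num_classes, head)
        self.conv = Conv1d(input_channels, width, kernel_size, dilation=dilation,
                           causal=True, rng=rng)
        self.relu = ReLU()
        self.pool = GlobalAvgPool()
        self.head = Linear(width, num_classes, rng=rng)

    def _layers(self):
        return [self.conv, self.head]

    def parameters(self):
        return [p for layer in self._layers() for _, p in layer.parameters()]

    def gradients(self):
        return [g for layer in self._layers() for _, g in layer.gradients()]

    def zero_grad(self):
        for g in self.gradients():
            g[...] = 0.0

    def get_state(self):
        return [p.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, s in zip(self.parameters(), state):
            p[...] = s

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.head.forward(self.pool.forward(self.relu.forward(self.conv.forward(x))))

    def backward(self, gscores: np.ndarray) -> None:
        g = self.pool.backward(self.head.backward(gscores))
        self.conv.backward(self.relu.backward(g))

    def predict_scores(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        parts = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(parts, axis=0)
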
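"""Independent oracles used by the test suite.

These are deliberately naive (loop-based / brute-force) implementations kept
separate from the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def naive_conv1d(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    dilation: int = 1,
    stride: int = 1,
    causal: bool = True,
) -> np.ndarray:
    """Triple-loop 1-D convolution oracle on a single [C, T] sample."""
    c_in, t = x.shape
    c_out, _, k = weights.shape
    pad = (k - 1) * dilation
    left = pad if causal else pad // 2
    t_out = (t - 1) // stride + 1
    out = np.zeros((c_out, t_out))
    for o in range(c_out):
        for ti in range(t_out):
            acc = bias[o]
            for ci in range(c_in):
                for j in range(k):
                    src = ti * stride - left + j * dilation
                    if 0 <= src < t:
                        acc += weights[o, ci, j] * x[ci, src]
            out[o, ti] = acc
    return out


def brute_force_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise concordance probability over all positive-negative pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def perturbation_footprint(layers, t_in: int, eps: float = 1.0) -> int:
    """Temporal span of inputs that influence the LAST output of a conv stack.

    ``layers`` is a list of built nn.Conv1d layers (applied in order); each
    input sample of an all-zero signal is perturbed in turn and the final
    output position checked for a change.  Weights are forced positive so
    contributions cannot cancel.  Returns last - first influencing position
    + 1 (sparse dilation patterns may skip positions inside the span).
    """
    for layer in layers:
        layer.weight[...] = np.abs(layer.weight) + 0.1
        layer.bias[...] = 0.0

    def run(x):
        h = x
        for layer in layers:
            h = layer.forward(h)
        return h

    base = run(np.zeros((1, layers[0].spec.in_channels, t_in)))
    hits = []
    for pos in range(t_in):
        x = np.zeros((1, layers[0].spec.in_channels, t_in))
        x[0, :, pos] = eps
        out = run(x)
        if not np.allclose(out[0, :, -1], base[0, :, -1]):
            hits.append(pos)
    return hits[-1] - hits[0] + 1 if hits else 0
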
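"""The densely connected, adaptively dilated causal convolutional network.

Topology
--------
* **entry block** — a plain (non-causal) convolution with kernel 7 and stride
  2 into ``2 * g`` channels, ReLU, then max pooling (window 3, stride 2).
* **four dense stages** (default 2, 6, 8 and 4 blocks).  Each *dense block*
  runs a causal bottleneck convolution (kernel ``block_kernel``, dilation 1,
  ``bottleneck_width_multiplier * g`` channels), ReLU, then a causal dilated
  convolution (kernel ``block_kernel``, dilation from the per-stage schedule)
  producing ``g`` new channels, ReLU; the new channels are concatenated onto
  the block input, so every later block sees all earlier feature maps.
* **transition block** after every stage — average pooling (window 2,
  stride 2) followed by a non-causal kernel-1 convolution that compresses the
  channel count by the factor ``compression``.
* **head** — global average pooling over time and a single affine map to the
  class scores.  Scores are raw; softmax/sigmoid live in the loss layer.

There is no batch normalisation and no dropout anywhere.

The per-stage dilation schedule is ``d_i = min(cap, 2^(i+2))`` with the block
index ``i`` restarting at 0 in every stage, so each stage spans contexts from
4 samples up to the cap (default 128).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .conv import ConvSpec, receptive_field
from .nn import AvgPool1d, Conv1d, GlobalAvgPool, Linear, MaxPool1d, ReLU

__all__ = [
    "HEAD_KINDS",
    "ModelConfig",
    "LayerPlan",
    "dilation_schedule",
    "channel_plan",
    "build_model",
    "Network",
    "save_checkpoint",
    "load_checkpoint",
]

HEAD_KINDS = ("multiclass-softmax", "binary", "multilabel-sigmoid")


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyper-parameters.

    ``growth_rate`` is the number of new channels each dense block adds;
    ``compression`` is the transition-block channel-keep fraction in (0, 1];
    ``dilation_cap`` bounds the dilation schedule and must be a power of two
    >= 4 (the schedule starts at 4).
    """

    input_channels: int
    num_classes: int
    head: str = "multiclass-softmax"
    blocks_per_stage: tuple[int, ...] = (2, 6, 8, 4)
    growth_rate: int = 32
    bottleneck_width_multiplier: int = 4
    dilation_cap: int = 128
    entry_kernel: int = 7
    block_kernel: int = 3
    compression: float = 0.5

    def __post_init__(self) -> None:
        if self.head not in HEAD_KINDS:
            raise ValueError(f"head must be one of {HEAD_KINDS}, got {self.head!r}")
        for name in (
            "input_channels",
            "num_classes",
            "growth_rate",
            "bottleneck_width_multiplier",
            "entry_kernel",
            "block_kernel",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"ModelConfig.{name} must be >= 1")
        bps = tuple(int(b) for b in self.blocks_per_stage)
        if not bps or any(b < 1 for b in bps):
            raise ValueError("blocks_per_stage must be non-empty with all entries >= 1")
        object.__setattr__(self, "blocks_per_stage", bps)
        cap = self.dilation_cap
        if cap < 4 or cap & (cap - 1):
            raise ValueError(f"dilation_cap must be a power of two >= 4, got {cap}")
        if not 0.0 < self.compression <= 1.0:
            raise ValueError(f"compression must be in (0, 1], got {self.compression}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks_per_stage"] = list(self.blocks_per_stage)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "blocks_per_stage" in d:
            d["blocks_per_stage"] = tuple(d["blocks_per_stage"])
        return cls(**d)


@dataclass
class LayerPlan:
    """Resolved per-layer specification of a built model."""

    entry_out: int
    stage_pre: list[int]     # channels entering each transition
    stage_post: list[int]    # channels leaving each transition
    head_in: int
    conv_specs: list[ConvSpec] = field(default_factory=list)
    pools: list[dict] = field(default_factory=list)


def dilation_schedule(num_blocks: int, cap: int) -> list[int]:
    """Per-stage dilation factors ``[min(cap, 2^(i+2)) for i in 0..B-1]``."""
    if num_blocks < 1:
        raise ValueError(f"num_blocks must be >= 1, got {num_blocks}")
    if cap < 4:
        raise ValueError(f"cap must be >= 4, got {cap}")
    return [min(cap, 2 ** (i + 2)) for i in range(num_blocks)]


def channel_plan(config: ModelConfig) -> LayerPlan:
    """Predict every channel count of the built model from the config alone.

    Entry emits ``2g``; a stage entered at ``C`` with ``B`` blocks leaves at
    ``C + B * g`` (concatenative growth); its transition keeps
    ``floor(compression * (C + B * g))`` channels.
    """
    g = config.growth_rate
    plan = LayerPlan(entry_out=2 * g, stage_pre=[], stage_post=[], head_in=0)
    plan.conv_specs.append(
        ConvSpec(config.input_channels, 2 * g, config.entry_kernel, 1, 2, causal=False)
    )
    plan.pools.append({"kind": "max", "window": 3, "stride": 2})
    c = 2 * g
    bw = config.bottleneck_width_multiplier * g
    for n_blocks in config.blocks_per_stage:
        dils = dilation_schedule(n_blocks, config.dilation_cap)
        for d in dils:
            plan.conv_specs.append(ConvSpec(c, bw, config.block_kernel, 1, 1, causal=True))
            plan.conv_specs.append(ConvSpec(bw, g, config.block_kernel, d, 1, causal=True))
            c += g
        plan.stage_pre.append(c)
        c_post = int(np.floor(config.compression * c))
        plan.pools.append({"kind": "avg", "window": 2, "stride": 2})
        plan.conv_specs.append(ConvSpec(c, c_post, 1, 1, 1, causal=False))
        plan.stage_post.append(c_post)
        c = c_post
    plan.head_in = c
    return plan


class _DenseBlock:
    """Bottleneck conv -> ReLU -> dilated causal conv -> ReLU -> concat."""

    def __init__(self, in_ch: int, g: int, bw: int, k: int, dilation: int,
                 rng: np.random.Generator) -> None:
        self.conv1 = Conv1d(in_ch, bw, k, dilation=1, causal=True, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(bw, g, k, dilation=dilation, causal=True, rng=rng)
        self.relu2 = ReLU()
        self.in_ch = in_ch

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        new = self.relu2.forward(self.conv2.forward(h))
        return np.concatenate([x, new], axis=1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gx, gnew = gout[:, : self.in_ch], gout[:, self.in_ch :]
        gh = self.conv2.backward(self.relu2.backward(gnew))
        return gx + self.conv1.backward(self.relu1.backward(gh))

    def layers(self):
        return [self.conv1, self.conv2]


class Network:
    """A built model: ordered layers, seeded parameters, batched forward/backward."""

    def __init__(self, config: ModelConfig, seed: int) -> None:
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        g = config.growth_rate
        bw = config.bottleneck_width_multiplier * g

        self.entry_conv = Conv1d(
            config.input_channels, 2 * g, config.entry_kernel, stride=2, causal=False, rng=rng
        )
        self.entry_relu = ReLU()
        self.entry_pool = MaxPool1d(window=3, stride=2)

        self.stages: list[list[_DenseBlock]] = []
        self.transitions: list[tuple[AvgPool1d, Conv1d]] = []
        c = 2 * g
        for n_blocks in config.blocks_per_stage:
            blocks = []
            for d in dilation_schedule(n_blocks, config.dilation_cap):
                blocks.append(_DenseBlock(c, g, bw, config.block_kernel, d, rng))
                c += g
            self.stages.append(blocks)
            c_post = int(np.floor(config.compression * c))
            self.transitions.append(
                (AvgPool1d(2, 2), Conv1d(c, c_post, 1, causal=False, rng=rng))
            )
            c = c_post
        self.head_pool = GlobalAvgPool()
        self.head = Linear(c, config.num_classes, rng=rng)
        self.plan = channel_plan(config)
        self._min_len: int | None = None

    # -- bookkeeping ---------------------------------------------------------

    def _layers(self):
        out = [self.entry_conv]
        for blocks, (pool, conv) in zip(self.stages, self.transitions):
            for b in blocks:
                out.extend(b.layers())
            out.append(conv)
        out.append(self.head)
        return out

    def parameters(self) -> list[np.ndarray]:
        ps = []
        for layer in self._layers():
            ps.extend(p for _, p in layer.parameters())
        return ps

    def gradients(self) -> list[np.ndarray]:
        gs = []
        for layer in self._layers():
            gs.extend(g for _, g in layer.gradients())
        return gs

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length does not match model parameters")
        for p, s in zip(params, state):
            if p.shape != s.shape:
                raise ValueError(f"state shape {s.shape} != parameter shape {p.shape}")
            p[...] = s

    def dilations(self) -> list[list[int]]:
        """Per-stage dilation factors actually instantiated in the blocks."""
        return [[b.conv2.spec.dilation for b in blocks] for blocks in self.stages]

    def _length_ok(self, t: int) -> bool:
        t = self.entry_conv.spec.out_length(t)
        if t < self.entry_pool.window:
            return False
        t = self.entry_pool.out_length(t)
        for pool, _ in self.transitions:
            if t < pool.window:
                return False
            t = pool.out_length(t)
        return t >= 1

    def min_input_length(self) -> int:
        """Smallest input length for which every pooling window is non-degenerate."""
        if self._min_len is None:
            t = 1
            while not self._length_ok(t):
                t += 1
            self._min_len = t
        return self._min_len

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, return_activations: bool = False):
        """Class scores for a batch ``[N, C, T]``; optionally the per-block
        concatenated activations keyed ``'stage{s}/block{b}'``."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3:
            raise ValueError(f"expected [N, C, T] batch, got shape {x.shape}")
        if x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"batch has {x.shape[1]} channels, model expects {self.config.input_channels}"
            )
        if x.shape[2] < self.min_input_length():
            raise ValueError(
                f"sequence length {x.shape[2]} is below the minimum supported "
                f"length {self.min_input_length()} for this configuration"
            )
        acts: dict[str, np.ndarray] = {}
        h = self.entry_pool.forward(self.entry_relu.forward(self.entry_conv.forward(x)))
        for si, (blocks, (pool, conv)) in enumerate(zip(self.stages, self.transitions)):
            for bi, block in enumerate(blocks):
                h = block.forward(h)
                if return_activations:
                    acts[f"stage{si}/block{bi}"] = h
            h = conv.forward(pool.forward(h))
        scores = self.head.forward(self.head_pool.forward(h))
        if return_activations:
            return scores, acts
        return scores

    def backward(self, gscores: np.ndarray) -> None:
        g = self.head_pool.backward(self.head.backward(gscores))
        for blocks, (pool, conv) in zip(reversed(self.stages), reversed(self.transitions)):
            g = pool.backward(conv.backward(g))
            for block in reversed(blocks):
                g = block.backward(g)
        g = self.entry_conv.backward(self.entry_relu.backward(self.entry_pool.backward(g)))

    def predict_scores(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        parts = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(parts, axis=0)

    def receptive_field(self) -> int:
        """Analytic receptive field of the full conv/pool stack."""
        specs: list[ConvSpec] = [self.entry_conv.spec]
        specs.append(ConvSpec(1, 1, 3, 1, 2, causal=False))  # max pool as pseudo-conv
        for blocks in self.stages:
            for b in blocks:
                specs.append(b.conv1.spec)
                specs.append(b.conv2.spec)
            specs.append(ConvSpec(1, 1, 2, 1, 2, causal=False))  # avg pool
        return receptive_field(specs)


def build_model(config: ModelConfig, seed: int) -> Network:
    """Construct the network with bit-reproducible, seeded initial weights."""
    return Network(config, seed)


def save_checkpoint(path: str | Path, model: Network, extra: dict | None = None) -> None:
    """Write parameters as .npy files plus a JSON sidecar (config + seed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    state = model.get_state()
    for i, p in enumerate(state):
        np.save(path / f"param_{i:04d}.npy", p)
    meta = {
        "config": model.config.to_dict(),
        "seed": model.seed,
        "num_arrays": len(state),
        "extra": extra or {},
    }
    (path / "checkpoint.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_checkpoint(path: str | Path) -> Network:
    path = Path(path)
    meta = json.loads((path / "checkpoint.json").read_text())
    model = build_model(ModelConfig.from_dict(meta["config"]), meta["seed"])
    state = [np.load(path / f"param_{i:04d}.npy") for i in range(meta["num_arrays"])]
    model.set_state(state)
    return model
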
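"""Architecture assembly: dilation schedule, channel bookkeeping, dense
connectivity, seeded determinism and causality through the built model."""

import numpy as np
import pytest
from scipy.special import softmax

from chronodense import (
    ModelConfig,
    build_model,
    channel_plan,
    dilation_schedule,
)


class TestDilationSchedule:
    @pytest.mark.parametrize(
        "num_blocks, cap, expected",
        [
            (2, 128, [4, 8]),
            (8, 128, [4, 8, 16, 32, 64, 128, 128, 128]),
            (1, 4, [4]),
            (6, 128, [4, 8, 16, 32, 64, 128]),
        ],
    )
    def test_known_values(self, num_blocks, cap, expected):
        assert dilation_schedule(num_blocks, cap) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            dilation_schedule(0, 128)
        with pytest.raises(ValueError):
            dilation_schedule(3, 2)


class TestChannelPlan:
    def test_default_config_hand_arithmetic(self):
        plan = channel_plan(ModelConfig(input_channels=1, num_classes=2))
        assert plan.entry_out == 64
        assert plan.stage_pre == [128, 256, 384, 320]
        assert plan.stage_post == [64, 128, 192, 160]
        assert plan.head_in == 160

    def test_no_compression_single_block(self):
        cfg = ModelConfig(input_channels=1, num_classes=2, blocks_per_stage=(1,),
                          growth_rate=8, compression=1.0)
        plan = channel_plan(cfg)
        assert plan.entry_out == 16
        assert plan.stage_pre == [24]
        assert plan.stage_post == [24]

    def test_floor_compression(self):
        cfg = ModelConfig(input_channels=1, num_classes=2, blocks_per_stage=(1,),
                          growth_rate=1, compression=0.5)
        plan = channel_plan(cfg)
        assert plan.entry_out == 2
        assert plan.stage_pre == [3]
        assert plan.stage_post == [1]  # floor(0.5 * 3)


class TestBuildModel:
    def test_default_block_and_stage_counts(self):
        model = build_model(ModelConfig(input_channels=1, num_classes=2), seed=0)
        assert [len(s) for s in model.stages] == [2, 6, 8, 4]
        assert sum(len(s) for s in model.stages) == 20
        assert len(model.transitions) == 4

    def test_dilation_audit_default_model(self):
        model = build_model(ModelConfig(input_channels=1, num_classes=2), seed=0)
        assert model.dilations() == [
            [4, 8],
            [4, 8, 16, 32, 64, 128],
            [4, 8, 16, 32, 64, 128, 128, 128],
            [4, 8, 16, 32],
        ]
        assert max(d for stage in model.dilations() for d in stage) == 128

    def test_seeded_builds_are_bit_identical(self, tiny_config):
        a = build_model(tiny_config, seed=42)
        b = build_model(tiny_config, seed=42)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)
        c = build_model(tiny_config, seed=43)
        assert any((pc != pa).any() for pa, pc in zip(a.parameters(), c.parameters()))

    def test_parameter_count_deterministic_and_matches_plan(self, shrunk_config):
        model = build_model(shrunk_config, seed=0)
        plan = model.plan
        expected = sum(
            s.out_channels * s.in_channels * s.kernel_size + s.out_channels
            for s in plan.conv_specs
        ) + shrunk_config.num_classes * (plan.head_in + 1)
        assert model.num_parameters() == expected
        assert model.num_parameters() == build_model(shrunk_config, seed=9).num_parameters()

    def test_channel_bookkeeping_random_configs(self, rng):
        """Measured concatenated widths equal the plan for 20 random configs."""
        for _ in range(20):
            n_stages = int(rng.integers(1, 4))
            cfg = ModelConfig(
                input_channels=int(rng.integers(1, 4)),
                num_classes=int(rng.integers(2, 6)),
                blocks_per_stage=tuple(int(rng.integers(1, 5)) for _ in range(n_stages)),
                growth_rate=int(rng.integers(2, 9)),
                bottleneck_width_multiplier=int(rng.integers(1, 5)),
                compression=float(rng.uniform(0.3, 1.0)),
            )
            model = build_model(cfg, seed=int(rng.integers(0, 1000)))
            plan = channel_plan(cfg)
            assert model.entry_conv.spec.out_channels == plan.entry_out
            for si, blocks in enumerate(model.stages):
                width = model.transitions[si][1].spec.in_channels
                assert width == plan.stage_pre[si]
                assert model.transitions[si][1].spec.out_channels == plan.stage_post[si]
                # each block consumes everything produced before it
                start = plan.entry_out if si == 0 else plan.stage_post[si - 1]
                for bi, block in enumerate(blocks):
                    assert block.conv1.spec.in_channels == start + bi * cfg.growth_rate
            assert model.head.weight.shape[1] == plan.head_in


class TestForward:
    def test_zeroed_head_gives_uniform_softmax(self, shrunk_config, rng):
        model = build_model(shrunk_config, seed=0)
        model.head.weight[...] = 0.0
        model.head.bias[...] = 0.0
        scores = model.forward(rng.normal(size=(3, 1, 256)))
        probs = softmax(scores, axis=1)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_batch_dimension_and_softmax_rows(self, shrunk_config, rng):
        model = build_model(shrunk_config, seed=0)
        scores = model.forward(rng.normal(size=(3, 1, 256)))
        assert scores.shape == (3, 4)
        np.testing.assert_allclose(softmax(scores, axis=1).sum(axis=1), 1.0, atol=1e-12)

    def test_channel_mismatch_errors(self, shrunk_config, rng):
        model = build_model(shrunk_config, seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.normal(size=(2, 3, 256)))

    def test_too_short_input_errors(self, rng):
        model = build_model(ModelConfig(input_channels=1, num_classes=2), seed=0)
        t_min = model.min_input_length()
        with pytest.raises(ValueError):
            model.forward(rng.normal(size=(1, 1, t_min - 1)))
        model.forward(rng.normal(size=(1, 1, t_min)))  # boundary length works

    def test_block_activations_causal_up_to_downsampling(self, shrunk_config, rng):
        """Two batches agreeing on [0, t*]: dense-block activations agree
        wherever the entry block's (non-causal, downsampling) halo allows.

        The entry conv (k=7, stride 2, symmetric pad 3) then max pool (3,
        stride 2) make pooled index v depend on inputs <= 4v + 7; everything
        after is causal, so activations of stage 0 agree for v <= (t*-7)//4.
        """
        model = build_model(shrunk_config, seed=0)
        t, t_star = 512, 256
        a = rng.normal(size=(1, 1, t))
        b = a.copy()
        b[:, :, t_star + 1 :] = rng.normal(size=t - t_star - 1)
        _, acts_a = model.forward(a, return_activations=True)
        _, acts_b = model.forward(b, return_activations=True)
        v_max = (t_star - 7) // 4
        for bi in range(len(model.stages[0])):
            key = f"stage0/block{bi}"
            np.testing.assert_array_equal(
                acts_a[key][:, :, : v_max + 1], acts_b[key][:, :, : v_max + 1]
            )


class TestDenseReuse:
    def test_block_input_passes_through_concatenation_unchanged(self, rng):
        cfg = ModelConfig(input_channels=1, num_classes=2, blocks_per_stage=(3,),
                          growth_rate=4)
        model = build_model(cfg, seed=0)
        x = rng.normal(size=(2, 1, 128))
        _, acts = model.forward(x, return_activations=True)
        g = cfg.growth_rate
        # block b's output contains block b-1's full output as a prefix
        for bi in range(1, 3):
            prev = acts[f"stage0/block{bi - 1}"]
            cur = acts[f"stage0/block{bi}"]
            np.testing.assert_array_equal(cur[:, : prev.shape[1]], prev)
            assert cur.shape[1] == prev.shape[1] + g

    def test_ablating_a_block_changes_all_later_blocks(self, rng):
        """Zeroing block j's contribution alters the inputs of every later
        block in the stage (concatenative connectivity, not additive)."""
        cfg = ModelConfig(input_channels=1, num_classes=2, blocks_per_stage=(4,),
                          growth_rate=4)
        model = build_model(cfg, seed=0)
        x = rng.normal(size=(2, 1, 128))
        _, base = model.forward(x, return_activations=True)
        j = 1
        model.stages[0][j].conv2.weight[...] = 0.0
        model.stages[0][j].conv2.bias[...] = 0.0
        _, ablated = model.forward(x, return_activations=True)
        g = cfg.growth_rate
        in0 = model.stages[0][0].in_ch
        for bi in range(j, 4):
            sl = slice(in0 + j * g, in0 + (j + 1) * g)  # block j's channels
            assert not np.array_equal(base[f"stage0/block{bi}"][:, sl],
                                      ablated[f"stage0/block{bi}"][:, sl])
        # channels produced before block j are untouched
        np.testing.assert_array_equal(
            base[f"stage0/block{j}"][:, : in0 + j * g],
            ablated[f"stage0/block{j}"][:, : in0 + j * g],
        )
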
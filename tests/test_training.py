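"""Losses, warm-restart schedule, clipping and the seeded fit loop."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import softmax

from chronodense import (
    TrainConfig,
    binary_loss,
    build_model,
    fit,
    smoothed_cross_entropy,
    warm_restart_lr,
)
from chronodense.training import clip_global_norm


class TestSmoothedCrossEntropy:
    def test_zero_smoothing_is_plain_cross_entropy(self, rng):
        scores = rng.normal(size=(16, 5))
        labels = rng.integers(0, 5, size=16)
        p = softmax(scores, axis=1)
        plain = -np.log(p[np.arange(16), labels]).mean()
        assert abs(smoothed_cross_entropy(scores, labels, 0.0) - plain) < 1e-12

    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.5, 0.9])
    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_uniform_scores_give_log_k(self, eps, k, rng):
        scores = np.full((8, k), 3.7)
        labels = rng.integers(0, k, size=8)
        assert abs(smoothed_cross_entropy(scores, labels, eps) - math.log(k)) < 1e-12

    def test_hand_computed_two_class_case(self):
        """N=1, K=2, scores (2, 0), label 0, eps=0.1 against a by-hand
        evaluation of the softmax and the two log terms."""
        ce0 = math.log(1.0 + math.exp(-2.0))       # -log p0
        ce1 = math.log(1.0 + math.exp(2.0))        # -log p1
        expected = 0.9 * ce0 + 0.1 * 0.5 * (ce0 + ce1)
        got = smoothed_cross_entropy(np.array([[2.0, 0.0]]), np.array([0]), 0.1)
        assert abs(got - expected) < 1e-12

    def test_label_out_of_range_errors(self):
        with pytest.raises(ValueError):
            smoothed_cross_entropy(np.zeros((2, 3)), np.array([0, 3]), 0.0)

    def test_minimized_by_smoothed_target_distribution(self):
        """For one-hot labels and fixed eps, the optimal prediction is the
        smoothed target itself (direct optimisation on a 3-class toy)."""
        eps = 0.3
        labels = np.array([0])

        res = minimize(
            lambda s: smoothed_cross_entropy(s[None, :], labels, eps),
            x0=np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
        )
        p_opt = softmax(res.x)
        target = np.array([1.0 - eps + eps / 3, eps / 3, eps / 3])
        np.testing.assert_allclose(p_opt, target, atol=1e-4)


class TestBinaryLoss:
    def test_zero_score_is_log_two(self):
        for label in (0.0, 1.0):
            got = binary_loss(np.array([0.0]), np.array([label]), 0.0)
            assert abs(got - math.log(2.0)) < 1e-12

    def test_perfect_large_scores_vanish(self):
        scores = np.array([50.0, -50.0])
        labels = np.array([1.0, 0.0])
        assert binary_loss(scores, labels, 0.0) < 1e-12

    def test_scalar_oracle_value(self):
        # -log sigmoid(1) = log(1 + e^-1)
        expected = math.log(1.0 + math.exp(-1.0))
        assert abs(binary_loss(np.array([1.0]), np.array([1.0]), 0.0) - expected) < 1e-12

    def test_multilabel_shape_and_smoothing(self, rng):
        scores = rng.normal(size=(6, 3))
        labels = (rng.uniform(size=(6, 3)) > 0.5).astype(float)
        loss = binary_loss(scores, labels, 0.2)
        assert np.isfinite(loss) and loss > 0

    def test_non_binary_labels_error(self):
        with pytest.raises(ValueError):
            binary_loss(np.zeros(3), np.array([0.0, 0.5, 1.0]), 0.0)


class TestWarmRestartSchedule:
    def test_starts_at_configured_rate(self):
        cfg = TrainConfig()
        assert warm_restart_lr(0.0, cfg) == pytest.approx(1e-4)

    def test_restart_epochs_hit_lr_max_exactly(self):
        cfg = TrainConfig(learning_rate=1e-4, restart_period=10, restart_mult=2)
        for epoch in (0, 10, 30, 70):  # cycle boundaries 10, 10+20, 10+20+40
            assert warm_restart_lr(epoch, cfg) == pytest.approx(1e-4, abs=0)

    def test_cycle_midpoints_hit_half_lr_max(self):
        cfg = TrainConfig(learning_rate=1e-4, restart_period=10, restart_mult=2,
                          eta_min=0.0)
        for mid in (5.0, 20.0, 50.0):  # midpoints of cycles of length 10, 20, 40
            assert warm_restart_lr(mid, cfg) == pytest.approx(5e-5, rel=1e-12)

    def test_monotone_decrease_within_cycle(self):
        cfg = TrainConfig()
        lrs = [warm_restart_lr(e, cfg) for e in np.linspace(0, 9.99, 50)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_eta_min_floor(self):
        cfg = TrainConfig(learning_rate=1e-3, eta_min=1e-5)
        assert warm_restart_lr(9.9999, cfg) >= 1e-5


class TestClipping:
    def test_post_clip_global_norm_bounded(self, rng):
        for _ in range(20):
            grads = [rng.normal(size=s) * 10 for s in ((3, 4), (7,), (2, 2, 5))]
            clip_global_norm(grads, 1.0)
            total = math.sqrt(sum(float((g * g).sum()) for g in grads))
            assert total <= 1.0 + 1e-6

    def test_small_gradients_untouched(self, rng):
        g = rng.normal(size=(4,)) * 1e-3
        orig = g.copy()
        clip_global_norm([g], 1.0)
        np.testing.assert_array_equal(g, orig)


class TestFit:
    def test_separable_two_class_reaches_high_accuracy(self, tiny_config,
                                                       separable_dataset):
        x, y = separable_dataset
        model = build_model(tiny_config, seed=0)
        cfg = TrainConfig(learning_rate=1e-3, epochs=20, batch_size=16, seed=0)
        result = fit(model, (x, y), (x, y), cfg)
        assert result.history[-1]["train_acc"] >= 0.99

    def test_same_seed_identical_history(self, tiny_config, separable_dataset):
        x, y = separable_dataset
        cfg = TrainConfig(learning_rate=1e-3, epochs=4, batch_size=16, seed=7)
        r1 = fit(build_model(tiny_config, seed=3), (x, y), (x, y), cfg)
        r2 = fit(build_model(tiny_config, seed=3), (x, y), (x, y), cfg)
        assert r1.history == r2.history

    def test_history_lr_follows_warm_restarts(self, tiny_config, separable_dataset):
        x, y = separable_dataset
        cfg = TrainConfig(learning_rate=1e-3, epochs=13, batch_size=32,
                          restart_period=4, restart_mult=2, seed=0)
        result = fit(build_model(tiny_config, seed=0), (x, y), None, cfg)
        lrs = [row["lr"] for row in result.history]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[4] == pytest.approx(1e-3)   # restart at T0
        assert lrs[4 + 8] == pytest.approx(1e-3)  # restart at T0 + T0*mult

    def test_tiny_clip_freezes_training(self, tiny_config, separable_dataset):
        x, y = separable_dataset
        model = build_model(tiny_config, seed=0)
        before = [p.copy() for p in model.parameters()]
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=16,
                          clip_max_norm=1e-8, seed=0)
        result = fit(model, (x, y), None, cfg)
        movement = max(np.abs(p - b).max() for p, b in zip(model.parameters(), before))
        # Adam's epsilon dominates the vanishing clipped gradients, so each
        # step is far below lr and the training loss stays nearly flat.
        assert movement < 5e-3
        losses = [row["train_loss"] for row in result.history]
        assert abs(losses[-1] - losses[0]) < 0.01

    def test_first_epoch_loss_includes_l2_term(self, tiny_config, separable_dataset):
        """The recorded loss equals data loss + weight_l2 * sum of squared
        parameters, checked against direct summation on a one-batch run."""
        x, y = separable_dataset
        model = build_model(tiny_config, seed=0)
        scores = model.forward(x)
        data_loss = smoothed_cross_entropy(scores, y, 0.1)
        l2 = sum(float((p * p).sum()) for p in model.parameters())
        expected = data_loss + 0.01 * l2
        cfg = TrainConfig(learning_rate=0.0, eta_min=0.0, epochs=1,
                          batch_size=len(x), weight_l2=0.01, seed=0)
        result = fit(build_model(tiny_config, seed=0), (x, y), None, cfg)
        assert result.history[0]["train_loss"] == pytest.approx(expected, rel=1e-12)

    def test_empty_dataset_errors(self, tiny_config):
        with pytest.raises(ValueError):
            fit(build_model(tiny_config, seed=0),
                (np.zeros((0, 1, 96)), np.zeros(0, dtype=int)), None, TrainConfig())

    def test_divergent_loss_reports_epoch(self, tiny_config, separable_dataset):
        x, y = separable_dataset
        model = build_model(tiny_config, seed=0)
        model.head.bias[...] = np.inf
        cfg = TrainConfig(epochs=2, batch_size=16, seed=0)
        with pytest.raises(RuntimeError, match="epoch 0"):
            fit(model, (x, y), None, cfg)
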
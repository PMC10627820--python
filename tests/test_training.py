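"""Sparse NLL loss, balance weights, normalization and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopyfuse.network import CanopyNet, NetworkConfig
from canopyfuse.training import (
    NormalizationStats,
    TrainConfig,
    compute_balance_weights,
    finetune_mean_head,
    sparse_nll_loss,
    train,
)


class TestSparseNLL:
    def test_perfect_prediction_unit_variance_is_zero(self):
        val = sparse_nll_loss((np.array([[3.0]]), np.array([[1.0]])),
                              np.array([[3.0]]))
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_residual_two_variance_two(self):
        val = sparse_nll_loss((np.array([[2.0]]), np.array([[2.0]])),
                              np.array([[0.0]]))
        assert val == pytest.approx(1.0 + 0.5 * np.log(2.0), rel=1e-12)

    def test_unlabeled_pixels_contribute_nothing(self):
        rng = np.random.default_rng(0)
        mean = rng.normal(size=(6, 6))
        var = rng.uniform(0.5, 2.0, size=(6, 6))
        y = np.full((6, 6), np.nan)
        y[2, 3] = 1.0
        y[4, 1] = -0.5
        base = sparse_nll_loss((mean, var), y)
        big_mean = np.pad(mean, (0, 10), constant_values=99.0)
        big_var = np.pad(var, (0, 10), constant_values=1.0)
        big_y = np.pad(y, (0, 10), constant_values=np.nan)
        assert sparse_nll_loss((big_mean, big_var), big_y) == pytest.approx(
            base, rel=1e-12)

    def test_zero_valid_pixels_is_an_error(self):
        with pytest.raises(ValueError):
            sparse_nll_loss((np.ones((2, 2)), np.ones((2, 2))),
                            np.full((2, 2), np.nan))

    def test_gradient_vanishes_at_true_mean(self):
        # finite-difference derivative of the loss w.r.t. mu at mu = y
        y = np.array([[4.0]])
        var = np.array([[1.7]])
        eps = 1e-6
        up = sparse_nll_loss((y + eps, var), y)
        down = sparse_nll_loss((y - eps, var), y)
        assert abs((up - down) / (2 * eps)) < 1e-8

    def test_balanced_equals_unbalanced_single_bin(self):
        rng = np.random.default_rng(1)
        mean = rng.normal(5.0, 0.2, size=(4, 4))
        var = rng.uniform(0.5, 2.0, size=(4, 4))
        y = rng.uniform(5.0, 5.9, size=(4, 4))  # all in bin [5, 6)
        w = compute_balance_weights(y)
        assert sparse_nll_loss((mean, var), y, weights=w) == pytest.approx(
            sparse_nll_loss((mean, var), y), rel=1e-12)


class TestBalanceWeights:
    def test_sqrt_inverse_frequency_hand_value(self):
        w = compute_balance_weights([0.5, 1.5, 1.2, 1.8, 1.4])
        np.testing.assert_allclose(w.q, [2.0 / 3.0, 1.0 / 3.0], rtol=1e-12)

    def test_uniform_counts_give_uniform_weights(self):
        labels = np.concatenate([np.full(7, k + 0.5) for k in range(5)])
        w = compute_balance_weights(labels)
        np.testing.assert_allclose(w.q, 1.0 / 5.0, rtol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 59.9), min_size=1, max_size=200))
    def test_weights_normalize(self, labels):
        w = compute_balance_weights(labels)
        assert w.q.sum() == pytest.approx(1.0, rel=1e-9)
        assert np.all(w.q[w.counts > 0] > 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_balance_weights([])


class TestNormalization:
    def test_round_trip(self):
        rng = np.random.default_rng(2)
        x = rng.normal(3.0, 2.0, size=(10, 4, 5, 5)).astype(np.float32)
        y = rng.uniform(0, 40, size=(10, 5, 5)).astype(np.float32)
        stats = NormalizationStats.fit(x, y)
        z = rng.uniform(0, 40, size=100)
        np.testing.assert_allclose(
            stats.denormalize_target(stats.normalize_target(z)), z, atol=1e-9)

    def test_rejects_label_free_fit(self):
        x = np.zeros((2, 1, 3, 3), np.float32)
        with pytest.raises(ValueError):
            NormalizationStats.fit(x, np.full((2, 3, 3), np.nan))


def _tiny_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    h = rng.uniform(0, 30, size=(n, 7, 7)).astype(np.float32)
    x = np.stack([0.1 + 0.02 * h + rng.normal(0, 0.01, h.shape),
                  0.5 - 0.01 * h + rng.normal(0, 0.01, h.shape)],
                 axis=1).astype(np.float32)
    y = np.full_like(h, np.nan)
    y[:, 3, 3] = h[:, 3, 3]
    return x, y


class TestTrainLoop:
    def test_schedule_arithmetic(self):
        cfg = TrainConfig(iterations=1000, milestone_fracs=(0.4, 0.7),
                          decay=0.1, base_lr=1e-4)
        assert cfg.lr_at(0) == pytest.approx(1e-4)
        assert cfg.lr_at(400) == pytest.approx(1e-5)
        assert cfg.lr_at(999) == pytest.approx(1e-6)

    def test_training_reduces_loss(self):
        x, y = _tiny_data()
        net = CanopyNet(NetworkConfig(in_channels=2, n_blocks=1, filters=8,
                                      seed=3))
        res = train(net, x, y, TrainConfig(iterations=200, batch_size=16,
                                           base_lr=3e-3, seed=1))
        assert res.losses[-20:].mean() < res.losses[:20].mean()

    def test_same_seed_identical_traces(self):
        x, y = _tiny_data()
        cfg = TrainConfig(iterations=30, batch_size=8, base_lr=1e-3, seed=4)
        traces = []
        for _ in range(2):
            net = CanopyNet(NetworkConfig(in_channels=2, n_blocks=1,
                                          filters=4, seed=3))
            traces.append(train(net, x, y, cfg).losses)
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_nonfinite_loss_aborts_with_diagnostics(self):
        x, y = _tiny_data()
        x[0, 0, 0, 0] = np.inf
        net = CanopyNet(NetworkConfig(in_channels=2, n_blocks=1, filters=4,
                                      seed=3))
        with pytest.raises(RuntimeError, match="iteration"):
            train(net, x, y, TrainConfig(iterations=10, batch_size=40, seed=0))


class TestFinetune:
    def test_only_mean_head_changes(self):
        x, y = _tiny_data()
        net = CanopyNet(NetworkConfig(in_channels=2, n_blocks=1, filters=8,
                                      seed=6))
        cfg = TrainConfig(iterations=50, batch_size=16, base_lr=3e-3, seed=2,
                          finetune_iterations=30)
        res = train(net, x, y, cfg)
        before = {name: p.copy() for name, p in net.named_parameters()}
        w = compute_balance_weights(y[np.isfinite(y)])
        finetune_mean_head(net, x, y, w, cfg, stats=res.stats)
        changed = 0
        for name, p in net.named_parameters():
            if name.startswith("head_mean."):
                changed += int(not np.array_equal(before[name], p))
            else:
                np.testing.assert_array_equal(before[name], p)
        assert changed > 0

    def test_weights_are_mandatory(self):
        x, y = _tiny_data()
        net = CanopyNet(NetworkConfig(in_channels=2, n_blocks=1, filters=4,
                                      seed=6))
        cfg = TrainConfig(iterations=5, finetune_iterations=5)
        res = train(net, x, y, cfg)
        with pytest.raises(ValueError):
            finetune_mean_head(net, x, y, None, cfg, stats=res.stats)
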
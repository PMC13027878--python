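"""Loss, schedule, EMA, gated checkpointing and early-stop behavior."""

import math

import numpy as np
import pytest

from srcorrect.dataset import TrainingPair
from srcorrect.errors import ConfigurationError, ShapeError
from srcorrect.nn import BatchNorm2d
from srcorrect.sdresnet import ModelConfig, build_model
from srcorrect.training import (
    CheckpointState,
    TrainConfig,
    ema_update,
    inference_weights,
    loss_fn,
    loss_grad,
    lr_schedule,
    train,
)


def tiny_pairs(n, seed=0, size=32):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        gt = rng.random((size, size))
        degraded = gt + 0.1 * rng.standard_normal((size, size))
        pairs.append(TrainingPair(degraded=degraded, gt=gt,
                                  phantom_id=f"phantom_{i:04d}",
                                  radius_used=0.0248, noise_seed=i))
    return pairs


def tiny_train(max_epochs, *, patience=20, gate=21, seed=0, n_train=4, n_val=2):
    model = build_model(ModelConfig(encoder_variant="small", seed=seed))
    config = TrainConfig(max_epochs=max_epochs, warmup_epochs=2, base_lr=1e-3,
                         patience=patience, checkpoint_gate_epoch=gate,
                         batch_size=2, seed=seed, patch=None, norm_scope="image")
    state, history = train(model, tiny_pairs(n_train), tiny_pairs(n_val, seed=50),
                           config)
    return model, state, history, config


class TestLoss:
    def test_zero_when_prediction_equals_target(self):
        x = np.random.default_rng(0).random((2, 1, 4, 4))
        assert loss_fn(x, x, "absolute") == 0.0
        assert loss_fn(x, x, "squared") == 0.0

    def test_constant_residual_values(self):
        pred = np.full((2, 1, 4, 4), 0.75)
        gt = np.full((2, 1, 4, 4), 0.25)
        assert loss_fn(pred, gt, "absolute") == pytest.approx(0.5)
        assert loss_fn(pred, gt, "squared") == pytest.approx(0.25)

    @pytest.mark.parametrize("variant", ["absolute", "squared"])
    def test_matches_scalar_loop_reference(self, variant):
        rng = np.random.default_rng(3)
        pred = rng.standard_normal((2, 1, 4, 4))
        gt = rng.standard_normal((2, 1, 4, 4))
        acc = 0.0
        for b in range(2):
            for i in range(4):
                for j in range(4):
                    d = pred[b, 0, i, j] - gt[b, 0, i, j]
                    acc += abs(d) if variant == "absolute" else d * d
        assert loss_fn(pred, gt, variant) == pytest.approx(acc / 32, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        pred = rng.standard_normal((1, 1, 3, 3))
        gt = rng.standard_normal((1, 1, 3, 3))
        for variant in ("absolute", "squared"):
            _, grad = loss_grad(pred, gt, variant)
            eps = 1e-7
            for idx in [(0, 0, 0, 0), (0, 0, 1, 2), (0, 0, 2, 1)]:
                p = pred.copy()
                p[idx] += eps
                up = loss_fn(p, gt, variant)
                p[idx] -= 2 * eps
                dn = loss_fn(p, gt, variant)
                assert grad[idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            loss_fn(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 5, 5)))


class TestLRSchedule:
    CFG = TrainConfig(max_epochs=100, warmup_epochs=5, base_lr=1e-3)

    def test_warmup_ramps_linearly_to_base(self):
        lrs = [lr_schedule(e, self.CFG) for e in range(5)]
        np.testing.assert_allclose(lrs, 1e-3 * np.arange(1, 6) / 5)

    def test_cosine_starts_at_base_lr(self):
        assert lr_schedule(5, self.CFG) == pytest.approx(1e-3)

    def test_final_epoch_decays_to_near_zero(self):
        assert lr_schedule(99, self.CFG) < 1e-3 * 6e-4

    def test_monotone_nonincreasing_after_warmup(self):
        lrs = [lr_schedule(e, self.CFG) for e in range(5, 100)]
        assert all(b <= a + 1e-18 for a, b in zip(lrs, lrs[1:]))

    def test_epoch_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            lr_schedule(100, self.CFG)


class TestEMAUpdate:
    def test_examples(self):
        assert ema_update({"w": np.array([0.0])}, {"w": np.array([1.0])}, 0.992)["w"][0] \
            == pytest.approx(0.008)
        same = ema_update({"w": np.array([2.0])}, {"w": np.array([2.0])}, 0.992)
        assert same["w"][0] == pytest.approx(2.0)

    def test_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            ema_update({"a": np.zeros(1)}, {"b": np.zeros(1)}, 0.992)


class TestTrainLoop:
    def test_short_run_before_gate_stores_only_last_weights(self):
        _, state, history, _ = tiny_train(6, gate=21)
        assert len(history) == 6
        assert state.best_raw_weights is None and state.best_ema_weights is None
        assert state.last_weights is not None and state.last_ema_weights is not None
        # inference falls back to the last EMA weights
        assert inference_weights(state) is state.last_ema_weights

    def test_gate_and_early_stop_consistent_with_history(self):
        _, state, history, config = tiny_train(40, gate=5, patience=3)
        losses = [h["val_loss_ema"] for h in history]
        best = math.inf
        streak = 0
        stop_epoch = None
        best_epoch = None
        for epoch, loss in enumerate(losses, start=1):
            improved = loss < best and (best - loss) / best > config.improvement_rtol \
                if math.isfinite(best) else True
            if improved:
                best = loss
                streak = 0
                if epoch > config.checkpoint_gate_epoch:
                    best_epoch = epoch
            else:
                streak += 1
            if streak > config.patience:
                stop_epoch = epoch
                break
        assert len(history) == (stop_epoch or 40)
        assert state.best_epoch == best_epoch
        if best_epoch is not None:
            assert state.best_epoch > config.checkpoint_gate_epoch

    def test_training_reduces_training_loss(self):
        _, _, history, _ = tiny_train(8)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_encoder_bn_running_stats_frozen_during_training(self):
        model = build_model(ModelConfig(encoder_variant="small", seed=1))
        enc_bns = [m for m in model.encoder.modules() if isinstance(m, BatchNorm2d)]
        dec_bns = [m for m in model.decoder.modules() if isinstance(m, BatchNorm2d)]
        enc_before = [bn.running_mean.copy() for bn in enc_bns]
        dec_before = [bn.running_mean.copy() for bn in dec_bns]
        config = TrainConfig(max_epochs=3, warmup_epochs=1, batch_size=2, seed=0,
                             patch=None, norm_scope="image")
        train(model, tiny_pairs(4), tiny_pairs(2, seed=50), config)
        for bn, before in zip(enc_bns, enc_before):
            np.testing.assert_array_equal(bn.running_mean, before)
        assert any(np.abs(bn.running_mean - before).max() > 0
                   for bn, before in zip(dec_bns, dec_before))

    def test_same_seed_reproduces_loss_trajectory(self):
        _, _, h1, _ = tiny_train(3)
        _, _, h2, _ = tiny_train(3)
        assert h1 == h2

    def test_nan_input_aborts_with_diagnostic(self):
        model = build_model(ModelConfig(encoder_variant="small", seed=1))
        bad = tiny_pairs(2)
        bad[0].degraded[0, 0] = np.nan
        config = TrainConfig(max_epochs=3, warmup_epochs=1, batch_size=2, seed=0,
                             patch=None, norm_scope="image")
        with pytest.raises(RuntimeError, match="non-finite"):
            train(model, bad, tiny_pairs(2, seed=50), config)

    def test_history_csv_written(self, tmp_path):
        model = build_model(ModelConfig(encoder_variant="small", seed=1))
        config = TrainConfig(max_epochs=2, warmup_epochs=1, batch_size=2, seed=0,
                             patch=None, norm_scope="image")
        log = tmp_path / "history.csv"
        train(model, tiny_pairs(2), tiny_pairs(2, seed=50), config, log_path=log)
        lines = log.read_text().strip().splitlines()
        assert lines[0] == "epoch,lr,train_loss,val_loss_ema"
        assert len(lines) == 3

    def test_empty_split_rejected(self):
        model = build_model(ModelConfig(encoder_variant="small", seed=1))
        config = TrainConfig(max_epochs=2, warmup_epochs=1)
        with pytest.raises(ConfigurationError):
            train(model, [], tiny_pairs(2), config)

    def test_empty_checkpoint_state_rejected(self):
        with pytest.raises(ConfigurationError):
            inference_weights(CheckpointState())
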
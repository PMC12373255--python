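"""Two-stage training: loss descent, determinism, the gradient penalty by
hand, and the critic/generator update schedule."""

import numpy as np
import pytest

from cardioaug.models import ModelConfig, build_networks
from cardioaug.nn.autograd import Tensor
from cardioaug.training import (TrainConfig, train_stage1, train_stage2,
                                gradient_penalty, NaNLossError)


def small_cfg(**kw):
    base = dict(k=3, backbone="mlp", width=24, cond_embed_dim=8, layers=2,
                heads=4)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal([2, 0, -1], 0.2, size=(80, 3)),
                   rng.normal([-2, 1, 1], 0.2, size=(80, 3))])
    y = np.repeat([0, 1], 80)
    return X, y


class TestStage1:
    def test_constant_input_fits_to_near_zero_loss(self):
        cfg = small_cfg(k=1)
        enc, dec, *_ = build_networks(cfg, 0)
        X = np.full((64, 1), 0.7)
        y = np.zeros(64, dtype=int)
        state = train_stage1(X, y, enc, dec,
                             TrainConfig(epochs=50, lr=1e-2, seed=0))
        assert state.loss_history["l_rec"][-1] < 1e-3

    def test_loss_trend_decreases(self, toy_data):
        X, y = toy_data
        enc, dec, *_ = build_networks(small_cfg(), 0)
        state = train_stage1(X, y, enc, dec,
                             TrainConfig(epochs=30, lr=1e-3, seed=1))
        h = state.loss_history["l_rec"]
        assert np.median(h[-5:]) < np.median(h[:5])

    def test_same_seed_identical_history(self, toy_data):
        X, y = toy_data
        histories = []
        for _ in range(2):
            enc, dec, *_ = build_networks(small_cfg(), 3)
            st = train_stage1(X, y, enc, dec,
                              TrainConfig(epochs=5, lr=1e-3, seed=3))
            histories.append(st.loss_history["l_rec"])
        assert histories[0] == histories[1]

    def test_pretraining_improves_reconstruction_10x(self):
        cfg = small_cfg(k=2)
        enc, dec, *_ = build_networks(cfg, 1)
        X = np.full((64, 2), [0.5, -0.3])
        y = np.zeros(64, dtype=int)

        def mse():
            out = dec.forward_numpy(enc.forward_numpy(X, y), y)
            return np.mean((out - X) ** 2)

        before = mse()
        train_stage1(X, y, enc, dec, TrainConfig(epochs=50, lr=1e-2, seed=0))
        assert mse() * 10 < before

    def test_nan_loss_aborts_with_diagnostic(self, toy_data):
        X, y = toy_data
        enc, dec, *_ = build_networks(small_cfg(), 0)
        with pytest.raises(NaNLossError, match="lr"):
            train_stage1(X * 1e200, y, enc, dec,
                         TrainConfig(epochs=3, lr=1e-3, seed=0))


class TestGradientPenalty:
    class _ScaledCritic:
        def __init__(self, slope):
            self.slope = slope

        def __call__(self, x, labels):
            return x * self.slope

    def test_slope_two_critic_gives_lambda(self):
        rng = np.random.default_rng(0)
        gp = gradient_penalty(self._ScaledCritic(2.0), np.zeros((8, 1)),
                              np.ones((8, 1)), None, 10.0, rng)
        assert gp.item() == pytest.approx(10.0, abs=1e-6)

    def test_unit_gradient_critic_gives_zero(self):
        rng = np.random.default_rng(0)
        gp = gradient_penalty(self._ScaledCritic(1.0), np.zeros((8, 1)),
                              np.ones((8, 1)), None, 10.0, rng)
        assert gp.item() == pytest.approx(0.0, abs=1e-9)

    def test_lambda_zero_gives_zero(self):
        rng = np.random.default_rng(0)
        gp = gradient_penalty(self._ScaledCritic(3.0), np.zeros((4, 1)),
                              np.ones((4, 1)), None, 0.0, rng)
        assert gp.item() == 0.0

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            gradient_penalty(self._ScaledCritic(1.0), np.zeros((4, 2)),
                             np.ones((3, 2)), None, 10.0, rng)


class TestStage2:
    @pytest.mark.parametrize("loss_mode", ["wgan_gp", "vanilla"])
    def test_losses_stay_finite_and_reproducible(self, toy_data, loss_mode):
        X, y = toy_data
        hists = []
        for _ in range(2):
            cfg = small_cfg()
            enc, dec, gen, disc = build_networks(cfg, 0)
            tc = TrainConfig(epochs=4, lr=1e-3, seed=2, loss_mode=loss_mode)
            train_stage1(X, y, enc, dec, TrainConfig(epochs=5, lr=1e-3, seed=2))
            st = train_stage2(X, y, enc, dec, gen, disc, cfg, tc)
            assert np.all(np.isfinite(st.loss_history["l_d"]))
            assert np.all(np.isfinite(st.loss_history["l_g"]))
            hists.append((st.loss_history["l_d"], st.loss_history["l_g"]))
        assert hists[0] == hists[1]

    def test_update_schedule_ratio(self, toy_data):
        X, y = toy_data
        cfg = small_cfg()
        enc, dec, gen, disc = build_networks(cfg, 0)
        tc = TrainConfig(epochs=3, lr=1e-3, seed=0, d_steps_per_g=2)
        st = train_stage2(X, y, enc, dec, gen, disc, cfg, tc)
        assert st.n_critic_updates == 2 * st.n_generator_updates

    def test_latent_space_discrimination_mode_runs(self, toy_data):
        X, y = toy_data
        cfg = small_cfg(discriminate_latent=True)
        enc, dec, gen, disc = build_networks(cfg, 0)
        train_stage1(X, y, enc, dec, TrainConfig(epochs=3, lr=1e-3, seed=0))
        st = train_stage2(X, y, enc, dec, gen, disc, cfg,
                          TrainConfig(epochs=2, lr=1e-3, seed=0))
        assert len(st.loss_history["l_d"]) == 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(d_steps_per_g=0)
        with pytest.raises(ValueError):
            TrainConfig(loss_mode="hinge")
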
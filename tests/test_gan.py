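"""WGAN-GP losses (closed forms) and pre-training behavior."""

import numpy as np
import pytest

from moladapt.fixtures import gaussian_latents
from moladapt.gan import (LatentWGAN, TrainConfig, critic_loss,
                          critic_spec, generator_loss, generator_spec,
                          gradient_penalty, load_mlp, pretrain, save_mlp)
from moladapt.nn import MLP, MLPSpec


def _linear_critic(w):
    w = np.atleast_2d(np.asarray(w, dtype=float))
    return MLP(MLPSpec((w.shape[1], 1)), [w], [np.zeros(1)])


def _constant_critic(c, width):
    # two-layer net with zero weights and output bias c: D(x) = c everywhere
    mlp = MLP(MLPSpec((width, 1)), [np.zeros((1, width))], [np.array([c])])
    return mlp


class TestGradientPenalty:
    def test_unit_norm_linear_critic_gives_zero(self):
        w = np.array([0.6, 0.8])  # ||w|| = 1
        critic = _linear_critic(w)
        rng = np.random.default_rng(0)
        real, fake = rng.standard_normal((2, 16, 2))
        assert gradient_penalty(critic, real, fake, 10.0, seed=1) == pytest.approx(0.0)

    def test_analytic_value_for_scaled_linear_critic(self):
        critic = _linear_critic([2.0, 0.0])
        rng = np.random.default_rng(3)
        real, fake = rng.standard_normal((2, 8, 2))
        # gradient is (2, 0) everywhere: penalty = 10 * (2 - 1)^2
        assert gradient_penalty(critic, real, fake, 10.0, seed=0) == pytest.approx(10.0)

    def test_zero_lambda_gives_zero(self):
        critic = _linear_critic([3.0, 1.0])
        x = np.ones((4, 2))
        assert gradient_penalty(critic, x, x + 1, 0.0, seed=0) == 0.0

    def test_nonnegative_for_random_critics(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            critic = MLP.build(critic_spec(3, (8, 8)), seed)
            real, fake = rng.standard_normal((2, 8, 3))
            assert gradient_penalty(critic, real, fake, 10.0, seed) >= 0.0

    def test_batch_mismatch_rejected(self):
        critic = _linear_critic([1.0, 0.0])
        with pytest.raises(ValueError):
            gradient_penalty(critic, np.ones((4, 2)), np.ones((3, 2)), 10.0, 0)


class TestLosses:
    def test_constant_critic_closed_forms(self):
        lam = 10.0
        critic = _constant_critic(2.5, width=2)
        rng = np.random.default_rng(1)
        real, fake = rng.standard_normal((2, 8, 2))
        # zero gradient everywhere: penalty = lam * (0 - 1)^2 = lam,
        # and the Wasserstein terms cancel
        assert critic_loss(critic, real, fake, lam, seed=0) == pytest.approx(lam)
        assert generator_loss(critic, fake) == pytest.approx(-2.5)

    def test_identical_batches_cancel_wasserstein_term(self):
        critic = MLP.build(critic_spec(2, (8,)), 0)
        x = np.random.default_rng(2).standard_normal((16, 2))
        loss = critic_loss(critic, x, x, 0.0, seed=0)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_empty_batch_rejected(self):
        critic = _linear_critic([1.0])
        with pytest.raises(ValueError):
            generator_loss(critic, np.empty((0, 1)))


class TestPretrain:
    def _small(self, seed=0):
        gen = MLP.build(generator_spec(4, 2, (8,)), seed)
        critic = MLP.build(critic_spec(2, (8,)), seed + 1)
        return gen, critic

    def test_zero_epochs_returns_states_unchanged(self):
        gen, critic = self._small()
        X = np.random.default_rng(0).standard_normal((32, 2))
        cfg = TrainConfig(epochs=0, batch_size=16, noise_dim=4)
        gen2, critic2, history = pretrain(X, gen, critic, cfg)
        assert history.empty
        assert gen2.param_hash() == gen.param_hash()
        assert critic2.param_hash() == critic.param_hash()

    def test_reproducible_from_seed(self):
        X = np.random.default_rng(0).standard_normal((64, 2))
        cfg = TrainConfig(epochs=3, batch_size=16, noise_dim=4, seed=5)
        runs = [pretrain(X, *self._small(), cfg=cfg) for _ in range(2)]
        assert runs[0][0].param_hash() == runs[1][0].param_hash()
        assert runs[0][1].param_hash() == runs[1][1].param_hash()

    def test_batch_size_larger_than_dataset_rejected(self):
        gen, critic = self._small()
        with pytest.raises(ValueError):
            pretrain(np.zeros((8, 2)), gen, critic,
                     TrainConfig(epochs=1, batch_size=16, noise_dim=4))

    def test_history_finite_and_epoch_long(self):
        X = gaussian_latents(np.zeros(2), np.eye(2), 64, seed=0)
        cfg = TrainConfig(epochs=4, batch_size=16, noise_dim=4, seed=0)
        _, _, history = pretrain(X, *self._small(), cfg=cfg)
        assert len(history) == 4
        assert np.isfinite(history[["critic_loss", "gp"]].to_numpy()).all()


class TestLatentWGANEstimator:
    def test_sklearn_param_interface(self):
        w = LatentWGAN(epochs=1, random_state=3)
        params = w.get_params()
        assert params["random_state"] == 3
        w.set_params(epochs=2)
        assert w.epochs == 2

    def test_fit_sets_trailing_underscore_attributes(self):
        X = np.random.default_rng(0).standard_normal((32, 3))
        w = LatentWGAN(noise_dim=4, gen_hidden=(8,), critic_hidden=(8,),
                       epochs=2, batch_size=16, random_state=0).fit(X)
        assert w.latent_dim_ == 3
        assert w.generator_.spec.widths[-1] == 3
        assert len(w.history_) == 2
        assert w.sample(5, random_state=1).shape == (5, 3)

    def test_sample_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            LatentWGAN().sample(3)

    def test_nonfinite_input_rejected(self):
        X = np.full((16, 2), np.nan)
        with pytest.raises(ValueError):
            LatentWGAN(epochs=1, batch_size=8).fit(X)


class TestCheckpoints:
    def test_save_load_bit_exact(self, tmp_path):
        mlp = MLP.build(critic_spec(3, (8, 8)), 0)
        mlp.frozen = [True, False, False]
        path = tmp_path / "critic.npz"
        save_mlp(path, mlp, meta={"stage": "pretrain"})
        back, header = load_mlp(path)
        assert back.param_hash() == mlp.param_hash()
        assert back.frozen == mlp.frozen
        assert header["meta"]["stage"] == "pretrain"
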
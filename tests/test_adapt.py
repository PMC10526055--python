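"""Adaptor mechanics, freezing contract, fine-tuning, baselines."""

import numpy as np
import pytest

from moladapt.adapt import (AdaptorState, FewShotAdapter, FinetuneConfig,
                            FreezePolicy, adaptor_forward, apply_freeze,
                            baseline_interpolate, baseline_random_sample,
                            finetune, finetune_latents, generate,
                            init_adaptor, sample_latents)
from moladapt.gan import LatentWGAN, critic_spec, generator_spec
from moladapt.nn import MLP, MLPSpec


class TestAdaptor:
    def test_identity_initialization(self):
        a = init_adaptor(3)
        assert np.array_equal(a.A, np.eye(3))
        assert np.array_equal(a.b, np.zeros(3))
        z = np.random.default_rng(0).standard_normal((7, 3))
        assert np.array_equal(adaptor_forward(z, a), z)

    def test_zero_input_returns_bias(self):
        a = AdaptorState(np.eye(2), np.array([4.0, -3.0]))
        assert np.array_equal(adaptor_forward(np.zeros((1, 2)), a),
                              [[4.0, -3.0]])

    def test_hand_computed_affine_map(self):
        a = AdaptorState(np.array([[2.0, 0.0], [0.0, 3.0]]),
                         np.array([1.0, -1.0]))
        out = adaptor_forward(np.array([[1.0, 1.0]]), a)
        assert np.array_equal(out, [[3.0, 2.0]])

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            init_adaptor(0)
        with pytest.raises(ValueError):
            AdaptorState(np.eye(3), np.zeros(2))
        with pytest.raises(ValueError):
            adaptor_forward(np.zeros((1, 3)), init_adaptor(2))


class TestFreezePolicy:
    def _nets(self):
        gen = MLP.build(generator_spec(4, 2, (8, 8)), 0)
        critic = MLP.build(critic_spec(2, (8, 8, 8)), 1)  # 4 weight layers
        return gen, critic

    def test_default_policy_freezes_generator_entirely(self):
        gen, critic = self._nets()
        gen_f, critic_f, census = apply_freeze(gen, critic, FreezePolicy())
        assert all(gen_f.frozen)
        assert census["generator_trainable_params"] == 0

    def test_last_n_critic_layers_trainable(self):
        gen, critic = self._nets()
        _, critic_f, census = apply_freeze(
            gen, critic, FreezePolicy(discriminator_trainable_last_n=2)
        )
        assert critic_f.frozen == [True, True, False, False]
        assert census["critic_trainable_layers"] == [2, 3]

    def test_zero_trainable_critic_layers_allowed(self):
        gen, critic = self._nets()
        _, critic_f, census = apply_freeze(
            gen, critic, FreezePolicy(discriminator_trainable_last_n=0)
        )
        assert all(critic_f.frozen)
        assert census["critic_trainable_params"] == 0

    def test_excessive_n_rejected(self):
        gen, critic = self._nets()
        with pytest.raises(ValueError):
            apply_freeze(gen, critic,
                         FreezePolicy(discriminator_trainable_last_n=9))


class TestFinetune:
    def _setup(self, seed=0):
        gen = MLP.build(generator_spec(4, 2, (8,)), seed)
        critic = MLP.build(critic_spec(2, (8, 8)), seed + 1)
        refs = np.random.default_rng(seed).standard_normal((8, 2)) + 2.0
        return gen, critic, refs

    def test_freeze_contract_bit_identical(self):
        gen, critic, refs = self._setup()
        gen_hash = gen.param_hash()
        frozen_layers = [0]  # 3 weight layers, last 2 trainable
        critic_hash = critic.param_hash(frozen_layers)
        cfg = FinetuneConfig(epochs=5, batch_size=2, seed=0)
        adaptor, critic_ft, history = finetune_latents(
            refs, gen, critic, init_adaptor(4), FreezePolicy(), cfg
        )
        assert gen.param_hash() == gen_hash
        assert critic_ft.param_hash(frozen_layers) == critic_hash
        # trainable layers did move
        assert critic_ft.param_hash() != critic.param_hash()
        assert len(history) == 5

    def test_identity_start_reproduces_pretrained_generation(self):
        gen, _, _ = self._setup()
        pre = gen.forward(np.random.default_rng(9).standard_normal((16, 4)))
        adapted = sample_latents(init_adaptor(4), gen, 16, seed=9)
        baseline = gen.forward(np.random.default_rng(9).standard_normal((16, 4)))
        assert np.array_equal(adapted, baseline)
        assert np.array_equal(pre, baseline)

    def test_reproducible_from_seed(self):
        gen, critic, refs = self._setup()
        cfg = FinetuneConfig(epochs=3, batch_size=2, seed=7)
        a1, c1, _ = finetune_latents(refs, gen, critic, init_adaptor(4),
                                     FreezePolicy(), cfg)
        a2, c2, _ = finetune_latents(refs, gen, critic, init_adaptor(4),
                                     FreezePolicy(), cfg)
        assert np.array_equal(a1.A, a2.A) and np.array_equal(a1.b, a2.b)
        assert c1.param_hash() == c2.param_hash()

    def test_zero_valid_references_rejected(self, codec):
        from moladapt.chem import MoleculeRecord

        gen = MLP.build(generator_spec(4, codec.latent_dim, (8,)), 0)
        critic = MLP.build(critic_spec(codec.latent_dim, (8, 8)), 1)
        bad = [MoleculeRecord.from_smiles("C(C")]
        with pytest.raises(ValueError):
            finetune(bad, codec, gen, critic, init_adaptor(4),
                     FreezePolicy(), FinetuneConfig(epochs=1))


class TestGenerate:
    def test_zero_requested_returns_empty(self, codec):
        gen = MLP.build(generator_spec(4, codec.latent_dim, (8,)), 0)
        assert generate(init_adaptor(4), gen, codec, n=0, seed=0) == []

    def test_deterministic_and_valid(self, codec):
        gen = MLP.build(generator_spec(4, codec.latent_dim, (8,)), 0)
        a = init_adaptor(4)
        m1 = generate(a, gen, codec, n=20, seed=3)
        m2 = generate(a, gen, codec, n=20, seed=3)
        assert [x.canonical_smiles for x in m1] == [x.canonical_smiles for x in m2]
        assert all(x.is_valid for x in m1)

    def test_identity_adaptor_matches_pretrained_generation(self, codec):
        gen = MLP.build(generator_spec(4, codec.latent_dim, (8,)), 0)
        via_adaptor = generate(init_adaptor(4), gen, codec, n=10, seed=5)
        z = np.random.default_rng(5).standard_normal((10, 4))
        direct = codec.decode(gen.forward(z))
        assert [m.canonical_smiles for m in via_adaptor] == [
            m.canonical_smiles for m in direct
        ]


class TestBaselines:
    def test_interpolation_stays_on_segments(self):
        refs = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        out = baseline_interpolate(refs, n=200, seed=0)
        assert out.shape == (200, 2)
        # every output is a convex combination of exactly two references
        for point in out:
            on_segment = False
            for i in range(3):
                for j in range(3):
                    if i == j:
                        continue
                    d = refs[j] - refs[i]
                    t = np.dot(point - refs[i], d) / np.dot(d, d)
                    if -1e-9 <= t <= 1 + 1e-9 and np.allclose(
                        refs[i] + t * d, point, atol=1e-9
                    ):
                        on_segment = True
            assert on_segment

    def test_identical_references_collapse(self):
        refs = np.tile([[1.0, 2.0]], (4, 1))
        out = baseline_interpolate(refs, n=50, seed=1)
        assert np.allclose(out, [1.0, 2.0])

    def test_interpolation_needs_two_references(self):
        with pytest.raises(ValueError):
            baseline_interpolate(np.ones((1, 2)), n=5, seed=0)

    def test_random_sampling_respects_radius(self):
        refs = np.array([[0.0, 0.0], [10.0, 10.0]])
        out = baseline_random_sample(refs, radius=1.5, n=300, seed=0)
        assert out.shape == (300, 2)
        dists = np.minimum(
            np.linalg.norm(out - refs[0], axis=1),
            np.linalg.norm(out - refs[1], axis=1),
        )
        assert (dists <= 1.5 + 1e-9).all()

    def test_zero_radius_copies_references(self):
        refs = np.array([[3.0, -1.0]])
        out = baseline_random_sample(refs, radius=0.0, n=10, seed=0)
        assert np.allclose(out, refs[0])


class TestFewShotAdapterEstimator:
    def test_requires_fitted_wgan(self):
        with pytest.raises(RuntimeError):
            FewShotAdapter(LatentWGAN()).fit(np.zeros((4, 2)))

    def test_fit_sample_and_freeze(self):
        X = np.random.default_rng(0).standard_normal((64, 2))
        wgan = LatentWGAN(noise_dim=4, gen_hidden=(8,), critic_hidden=(8, 8),
                          epochs=2, batch_size=16, random_state=0).fit(X)
        gen_hash = wgan.generator_.param_hash()
        adapter = FewShotAdapter(wgan, epochs=3, batch_size=2,
                                 random_state=1).fit(X[:5] + 3.0)
        assert adapter.adaptor_.A.shape == (4, 4)
        assert wgan.generator_.param_hash() == gen_hash
        sample = adapter.sample(12, random_state=2)
        assert sample.shape == (12, 2)
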
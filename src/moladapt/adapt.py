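"""Few-shot generative domain adaptation via an affine molecule adaptor.

Instead of fine-tuning the whole generator on a handful of reference
molecules (which overfits), the pre-trained generator G is frozen and a
lightweight affine *adaptor*

    z' = A z + b

is inserted in front of it: the adaptor re-shapes the input-noise
distribution so that G(A z + b) lands in the reference region of latent
space, while G's decoding knowledge — and hence the diversity of its
outputs — is preserved.  On the critic side only the last few layers are
trainable (the early layers keep their general feature extraction).  The
fine-tuning objective is the same WGAN-GP loss as pre-training, with the
encoded references as the real distribution.

Constrained generation then decodes G(A z + b) for fresh noise z:
molecules = decode(G(adaptor(z))).

Baselines: latent interpolation between reference pairs, and uniform
sampling inside L2 balls around the references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .chem import MoleculeRecord
from .codec import LatentCodec
from .gan import LatentWGAN, critic_update
from .nn import MLP, Adam


@dataclass
class AdaptorState:
    """The affine noise-space map: A (noise_dim × noise_dim), b (noise_dim)."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        d = self.b.shape[0]
        if self.A.shape != (d, d):
            raise ValueError(f"A shape {self.A.shape} inconsistent with b ({d},)")
        if not (np.isfinite(self.A).all() and np.isfinite(self.b).all()):
            raise ValueError("adaptor parameters must be finite")

    @property
    def noise_dim(self) -> int:
        return self.b.shape[0]

    def copy(self) -> "AdaptorState":
        return AdaptorState(self.A.copy(), self.b.copy())


@dataclass(frozen=True)
class FreezePolicy:
    """What is trainable during fine-tuning.  Default: adaptor plus the
    last two critic layers; the generator is entirely frozen."""

    generator_trainable: bool = False
    discriminator_trainable_last_n: int = 2
    adaptor_trainable: bool = True


@dataclass(frozen=True)
class FinetuneConfig:
    """Fine-tuning hyperparameters (40 epochs, mini-batch 1 by default; the
    learning rate defaults to the pre-training rate)."""

    epochs: int = 40
    batch_size: int = 1
    learning_rate: float = 1e-3
    gp_lambda: float = 10.0
    critic_steps_per_gen_step: int = 1
    adam_betas: tuple[float, float] = (0.0, 0.9)
    seed: int = 0
    #: keep an exponential moving average of the adaptor iterates (0 = off)
    ema_decay: float = 0.995
    #: linearly anneal learning rates to zero over the run
    lr_decay: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError(f"invalid fine-tune configuration: {self}")


def init_adaptor(noise_dim: int) -> AdaptorState:
    """Identity adaptor (A = I, b = 0): the adapted model starts out exactly
    equal to the pre-trained model."""
    if noise_dim < 1:
        raise ValueError("noise_dim must be >= 1")
    return AdaptorState(np.eye(noise_dim), np.zeros(noise_dim))


def adaptor_forward(z: np.ndarray, adaptor: AdaptorState) -> np.ndarray:
    """Row-wise affine map A·z + b."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != adaptor.noise_dim:
        raise ValueError(
            f"noise width {z.shape[1]} != adaptor dim {adaptor.noise_dim}"
        )
    return z @ adaptor.A.T + adaptor.b


def apply_freeze(generator: MLP, critic: MLP,
                 policy: FreezePolicy) -> tuple[MLP, MLP, dict]:
    """Set per-layer freeze flags; returns copies plus a trainable census."""
    n_layers = critic.spec.n_weight_layers
    last_n = policy.discriminator_trainable_last_n
    if not 0 <= last_n <= n_layers:
        raise ValueError(
            f"discriminator_trainable_last_n={last_n} exceeds {n_layers} layers"
        )
    generator = generator.copy()
    critic = critic.copy()
    generator.frozen = [not policy.generator_trainable] * generator.spec.n_weight_layers
    critic.frozen = [k < n_layers - last_n for k in range(n_layers)]

    def _count(mlp: MLP, trainable: bool) -> int:
        return sum(
            w.size + b.size
            for w, b, f in zip(mlp.weights, mlp.biases, mlp.frozen)
            if f != trainable
        )

    census = {
        "generator_trainable_params": _count(generator, True),
        "critic_trainable_params": _count(critic, True),
        "critic_trainable_layers": [k for k, f in enumerate(critic.frozen) if not f],
        "adaptor_trainable": policy.adaptor_trainable,
    }
    return generator, critic, census


def finetune_latents(ref_latents: np.ndarray, generator: MLP, critic: MLP,
                     adaptor: AdaptorState, policy: FreezePolicy,
                     cfg: FinetuneConfig) -> tuple[AdaptorState, MLP, pd.DataFrame]:
    """Adapt on already-encoded reference latent vectors.

    Real batches are drawn with replacement from the references (so 5-shot
    and 100-shot runs share one code path); fake batches are
    G(adaptor(z)).  The generator is never modified; frozen critic layers
    are bit-identical before and after.
    """
    ref_latents = np.atleast_2d(np.asarray(ref_latents, dtype=float))
    if ref_latents.shape[0] < 1:
        raise ValueError("need at least one reference latent vector")
    if ref_latents.shape[1] != generator.spec.widths[-1]:
        raise ValueError("reference latent width != generator output width")
    noise_dim = generator.spec.widths[0]
    if adaptor.noise_dim != noise_dim:
        raise ValueError("adaptor dimension != generator noise input width")

    generator, critic, _ = apply_freeze(generator, critic, policy)
    adaptor = adaptor.copy()
    rng = np.random.default_rng(cfg.seed)
    d_opt = Adam(critic.weights + critic.biases, lr=cfg.learning_rate,
                 betas=cfg.adam_betas)
    a_opt = Adam([adaptor.A, adaptor.b], lr=cfg.learning_rate,
                 betas=cfg.adam_betas)

    from .gan import _EMA

    ema = _EMA([adaptor.A, adaptor.b], cfg.ema_decay)
    n_refs = ref_latents.shape[0]
    steps_per_epoch = max(1, -(-n_refs // cfg.batch_size))  # ceil division
    rows = []
    step = 0
    for epoch in range(cfg.epochs):
        if cfg.lr_decay:
            factor = 1.0 - epoch / cfg.epochs
            d_opt.lr = cfg.learning_rate * factor
            a_opt.lr = cfg.learning_rate * factor
        d_losses, g_losses, gps = [], [], []
        for _ in range(steps_per_epoch):
            idx = rng.integers(0, n_refs, size=cfg.batch_size)
            real = ref_latents[idx]
            z = rng.standard_normal((cfg.batch_size, noise_dim))
            fake = generator.forward(adaptor_forward(z, adaptor))
            d_loss, gp = critic_update(critic, d_opt, real, fake,
                                       cfg.gp_lambda, rng)
            d_losses.append(d_loss)
            gps.append(gp)
            step += 1
            if policy.adaptor_trainable and step % cfg.critic_steps_per_gen_step == 0:
                g_losses.append(
                    _adaptor_update(adaptor, a_opt, generator, critic, rng,
                                    cfg.batch_size, noise_dim)
                )
                ema.update([adaptor.A, adaptor.b])
        rows.append(
            {
                "epoch": epoch,
                "critic_loss": float(np.mean(d_losses)),
                "gen_loss": float(np.mean(g_losses)) if g_losses else np.nan,
                "gp": float(np.mean(gps)),
            }
        )
    history = pd.DataFrame(rows, columns=["epoch", "critic_loss", "gen_loss", "gp"])
    ema.write_back([adaptor.A, adaptor.b])
    return adaptor, critic, history


def _adaptor_update(adaptor: AdaptorState, a_opt: Adam, generator: MLP,
                    critic: MLP, rng: np.random.Generator, batch_size: int,
                    noise_dim: int) -> float:
    """One Adam step on (A, b) for loss −mean D(G(A z + b))."""
    z = rng.standard_normal((batch_size, noise_dim))
    z_prime = adaptor_forward(z, adaptor)
    fake, g_cache = generator.forward(z_prime, want_cache=True)
    out, d_cache = critic.forward(fake, want_cache=True)
    _, _, grad_fake = critic.backward(
        d_cache, np.full((batch_size, 1), -1.0 / batch_size)
    )
    _, _, grad_zp = generator.backward(g_cache, grad_fake)
    grad_A = grad_zp.T @ z
    grad_b = grad_zp.sum(axis=0)
    a_opt.step([adaptor.A, adaptor.b], [grad_A, grad_b])
    return float(-out.mean())


def finetune(refs: list[MoleculeRecord], codec: LatentCodec, generator: MLP,
             critic: MLP, adaptor: AdaptorState, policy: FreezePolicy,
             cfg: FinetuneConfig) -> tuple[AdaptorState, MLP, pd.DataFrame]:
    """Few-shot adaptation on reference molecules (encoded by the codec)."""
    valid = [r for r in refs if r.is_valid]
    if not valid:
        raise ValueError("zero valid reference molecules")
    return finetune_latents(codec.encode(valid), generator, critic, adaptor,
                            policy, cfg)


def sample_latents(adaptor: AdaptorState, generator: MLP, n: int,
                   seed: int) -> np.ndarray:
    """Latent vectors G(A z + b) for fresh z ~ N(0, I)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, generator.spec.widths[-1]))
    z = rng.standard_normal((n, generator.spec.widths[0]))
    return generator.forward(adaptor_forward(z, adaptor))


def generate(adaptor: AdaptorState, generator: MLP, codec: LatentCodec,
             n: int = 1000, seed: int = 0) -> list[MoleculeRecord]:
    """Constrained generation: decode(G(adaptor(z))) for n noise draws."""
    latents = sample_latents(adaptor, generator, n, seed)
    if latents.shape[0] == 0:
        return []
    if codec.latent_dim != generator.spec.widths[-1]:
        raise ValueError("codec latent_dim != generator output width")
    return codec.decode(latents)


def baseline_interpolate(ref_latents: np.ndarray, n: int,
                         seed: int) -> np.ndarray:
    """Uniform convex combinations of random reference pairs (i ≠ j)."""
    ref_latents = np.atleast_2d(np.asarray(ref_latents, dtype=float))
    k = ref_latents.shape[0]
    if k < 2:
        raise ValueError("interpolation needs at least two references")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, k, size=n)
    j = (i + rng.integers(1, k, size=n)) % k  # guaranteed j != i
    t = rng.uniform(size=(n, 1))
    return t * ref_latents[i] + (1.0 - t) * ref_latents[j]


def baseline_random_sample(ref_latents: np.ndarray, radius: float, n: int,
                           seed: int) -> np.ndarray:
    """References plus uniform perturbations inside an L2 ball."""
    ref_latents = np.atleast_2d(np.asarray(ref_latents, dtype=float))
    if ref_latents.shape[0] < 1:
        raise ValueError("need at least one reference")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    rng = np.random.default_rng(seed)
    d = ref_latents.shape[1]
    idx = rng.integers(0, ref_latents.shape[0], size=n)
    direction = rng.standard_normal((n, d))
    direction /= np.maximum(np.linalg.norm(direction, axis=1, keepdims=True), 1e-12)
    # U^(1/d) radial law gives uniform density over the ball
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / d)
    return ref_latents[idx] + r * direction


class FewShotAdapter(BaseEstimator):
    """Scikit-learn-style wrapper: fit an adaptor to few reference latents.

    Built on a fitted :class:`LatentWGAN` (whose generator stays frozen);
    ``fit(X)`` runs adversarial fine-tuning with the rows of ``X`` as the
    target distribution, ``sample(n)`` draws adapted latent vectors.

    Fitted attributes: ``adaptor_``, ``critic_``, ``history_``.
    """

    def __init__(self, wgan: LatentWGAN, epochs: int = 40, batch_size: int = 1,
                 learning_rate: float = 1e-3, gp_lambda: float = 10.0,
                 disc_last_n: int = 2, critic_steps: int = 1,
                 adam_betas: tuple[float, float] = (0.0, 0.9),
                 random_state: int | None = None):
        self.wgan = wgan
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.gp_lambda = gp_lambda
        self.disc_last_n = disc_last_n
        self.critic_steps = critic_steps
        self.adam_betas = adam_betas
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "FewShotAdapter":
        if not hasattr(self.wgan, "generator_"):
            raise RuntimeError("the underlying LatentWGAN must be fitted first")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        cfg = FinetuneConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            gp_lambda=self.gp_lambda,
            critic_steps_per_gen_step=self.critic_steps,
            adam_betas=tuple(self.adam_betas),
            seed=0 if self.random_state is None else int(self.random_state),
        )
        policy = FreezePolicy(discriminator_trainable_last_n=self.disc_last_n)
        adaptor = init_adaptor(self.wgan.generator_.spec.widths[0])
        self.adaptor_, self.critic_, self.history_ = finetune_latents(
            X, self.wgan.generator_, self.wgan.critic_, adaptor, policy, cfg
        )
        return self

    def sample(self, n_samples: int, random_state: int | None = None) -> np.ndarray:
        if not hasattr(self, "adaptor_"):
            raise RuntimeError("FewShotAdapter is not fitted")
        seed = self.random_state if random_state is None else random_state
        return sample_latents(self.adaptor_, self.wgan.generator_,
                              int(n_samples), 0 if seed is None else int(seed))
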
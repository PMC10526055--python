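"""Latent-space Wasserstein GAN with gradient penalty.

The generative model never sees molecular graphs: a frozen codec maps
molecules to latent vectors, and the GAN is trained purely on those vectors.
The critic loss is

    L = E[D(r_G)] - E[D(r_E)] + λ E[(‖∇_r̂ D(r̂)‖₂ - 1)²]

with r_E real latents, r_G = G(z) generated latents, z ~ N(0, I), and r̂
uniformly interpolated between paired real and fake samples.  The generator
minimizes -E[D(r_G)].  Training alternates several critic steps per
generator step using Adam.

:class:`LatentWGAN` wraps pre-training in a scikit-learn estimator
(``fit`` on a latent matrix, ``sample`` to draw new latents).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .nn import MLP, MLPSpec, mlp_optimizer, mlp_step

#: architecture defaults: width lists include input and output widths
DEFAULT_NOISE_DIM = 100
DEFAULT_GEN_HIDDEN = (128, 256, 256, 512, 256)
DEFAULT_CRITIC_HIDDEN = (128, 256, 128)


@dataclass(frozen=True)
class TrainConfig:
    """Pre-training hyperparameters (WGAN-GP published defaults where the
    method description is silent: λ=10, 5 critic steps, Adam betas (0, 0.9))."""

    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    gp_lambda: float = 10.0
    critic_steps_per_gen_step: int = 5
    adam_betas: tuple[float, float] = (0.0, 0.9)
    seed: int = 0
    noise_dim: int = DEFAULT_NOISE_DIM
    #: the returned generator is an exponential moving average of the
    #: training iterates (standard GAN practice for final-iterate stability);
    #: set to 0 to return the last iterate instead
    ema_decay: float = 0.995
    #: linearly anneal both learning rates to zero over the run
    lr_decay: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0 or min(
            self.batch_size, self.critic_steps_per_gen_step, self.noise_dim
        ) < 1 or self.learning_rate <= 0 or self.gp_lambda < 0:
            raise ValueError(f"invalid training configuration: {self}")


def generator_spec(noise_dim: int, latent_dim: int,
                   hidden: tuple[int, ...] = DEFAULT_GEN_HIDDEN) -> MLPSpec:
    return MLPSpec((noise_dim, *hidden, latent_dim), hidden_activation="tanh")


def critic_spec(latent_dim: int,
                hidden: tuple[int, ...] = DEFAULT_CRITIC_HIDDEN) -> MLPSpec:
    return MLPSpec((latent_dim, *hidden, 1), hidden_activation="leaky_relu")


def _check_batches(real: np.ndarray, fake: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    real = np.atleast_2d(np.asarray(real, dtype=float))
    fake = np.atleast_2d(np.asarray(fake, dtype=float))
    if real.size == 0 or fake.size == 0:
        raise ValueError("empty latent batch")
    if real.shape != fake.shape:
        raise ValueError(f"batch shape mismatch: {real.shape} vs {fake.shape}")
    return real, fake


def interpolate_batches(real: np.ndarray, fake: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """r̂ = ε·real + (1-ε)·fake with ε ~ U(0,1) per pair."""
    real, fake = _check_batches(real, fake)
    eps = rng.uniform(size=(real.shape[0], 1))
    return eps * real + (1.0 - eps) * fake


def gradient_penalty(critic: MLP, real: np.ndarray, fake: np.ndarray,
                     gp_lambda: float, seed: int) -> float:
    """λ·mean((‖∇_r̂ D(r̂)‖₂ − 1)²) on freshly drawn interpolates."""
    rng = np.random.default_rng(seed)
    interp = interpolate_batches(real, fake, rng)
    _, cache = critic.forward(interp, want_cache=True)
    penalty, _, _ = critic.gradient_penalty_backward(cache, gp_lambda)
    return penalty


def critic_loss(critic: MLP, real: np.ndarray, fake: np.ndarray,
                gp_lambda: float, seed: int) -> float:
    """mean D(fake) − mean D(real) + gradient penalty."""
    real, fake = _check_batches(real, fake)
    wasserstein = float(critic.forward(fake).mean() - critic.forward(real).mean())
    return wasserstein + gradient_penalty(critic, real, fake, gp_lambda, seed)


def generator_loss(critic: MLP, fake: np.ndarray) -> float:
    """−mean D(fake)."""
    fake = np.atleast_2d(np.asarray(fake, dtype=float))
    if fake.size == 0:
        raise ValueError("empty latent batch")
    return float(-critic.forward(fake).mean())


def critic_update(critic: MLP, opt, real: np.ndarray, fake: np.ndarray,
                  gp_lambda: float, rng: np.random.Generator) -> tuple[float, float]:
    """One critic Adam step; returns (critic loss, penalty term)."""
    real, fake = _check_batches(real, fake)
    batch = real.shape[0]

    out_fake, cache_fake = critic.forward(fake, want_cache=True)
    out_real, cache_real = critic.forward(real, want_cache=True)
    gw_f, gb_f, _ = critic.backward(cache_fake, np.full((batch, 1), 1.0 / batch))
    gw_r, gb_r, _ = critic.backward(cache_real, np.full((batch, 1), -1.0 / batch))

    interp = interpolate_batches(real, fake, rng)
    _, cache_i = critic.forward(interp, want_cache=True)
    penalty, gw_p, gb_p = critic.gradient_penalty_backward(cache_i, gp_lambda)

    gw = [a + b + c for a, b, c in zip(gw_f, gw_r, gw_p)]
    gb = [a + b + c for a, b, c in zip(gb_f, gb_r, gb_p)]
    mlp_step(opt, critic, gw, gb)
    loss = float(out_fake.mean() - out_real.mean()) + penalty
    return loss, penalty


def pretrain(real_latents: np.ndarray, generator: MLP, critic: MLP,
             cfg: TrainConfig) -> tuple[MLP, MLP, pd.DataFrame]:
    """Alternating WGAN-GP training on a fixed pool of real latent vectors.

    Returns updated copies of the networks and a per-epoch loss history
    (columns: epoch, critic_loss, gen_loss, gp).  Fully reproducible from
    ``cfg.seed``.
    """
    real_latents = np.atleast_2d(np.asarray(real_latents, dtype=float))
    n = real_latents.shape[0]
    if cfg.batch_size > n:
        raise ValueError(f"batch_size {cfg.batch_size} exceeds dataset size {n}")
    if real_latents.shape[1] != generator.spec.widths[-1]:
        raise ValueError("generator output width != latent width")

    generator = generator.copy()
    critic = critic.copy()
    rng = np.random.default_rng(cfg.seed)
    g_opt = mlp_optimizer(generator, cfg.learning_rate, cfg.adam_betas)
    d_opt = mlp_optimizer(critic, cfg.learning_rate, cfg.adam_betas)
    ema = _EMA(generator.weights + generator.biases, cfg.ema_decay)

    rows = []
    step = 0
    for epoch in range(cfg.epochs):
        if cfg.lr_decay:
            factor = 1.0 - epoch / cfg.epochs
            g_opt.lr = cfg.learning_rate * factor
            d_opt.lr = cfg.learning_rate * factor
        order = rng.permutation(n)
        d_losses, g_losses, gps = [], [], []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            real = real_latents[order[start : start + cfg.batch_size]]
            z = rng.standard_normal((cfg.batch_size, cfg.noise_dim))
            fake = generator.forward(z)
            d_loss, gp = critic_update(
                critic, d_opt, real, fake, cfg.gp_lambda, rng
            )
            d_losses.append(d_loss)
            gps.append(gp)
            step += 1
            if step % cfg.critic_steps_per_gen_step == 0:
                g_losses.append(
                    _generator_update(generator, g_opt, critic, rng,
                                      cfg.batch_size, cfg.noise_dim)
                )
                ema.update(generator.weights + generator.biases)
        rows.append(
            {
                "epoch": epoch,
                "critic_loss": float(np.mean(d_losses)) if d_losses else np.nan,
                "gen_loss": float(np.mean(g_losses)) if g_losses else np.nan,
                "gp": float(np.mean(gps)) if gps else np.nan,
            }
        )
    history = pd.DataFrame(rows, columns=["epoch", "critic_loss", "gen_loss", "gp"])
    ema.write_back(generator.weights + generator.biases)
    return generator, critic, history


class _EMA:
    """Exponential moving average of a parameter list (no-op at decay 0)."""

    def __init__(self, params: list[np.ndarray], decay: float):
        self.decay = decay
        self.shadow = [p.copy() for p in params] if decay > 0 else None
        self.started = False

    def update(self, params: list[np.ndarray]) -> None:
        if self.shadow is None:
            return
        if not self.started:
            # the shadow starts at the first post-update iterate, not at the
            # random initialization
            for s, p in zip(self.shadow, params):
                s[...] = p
            self.started = True
            return
        for s, p in zip(self.shadow, params):
            s *= self.decay
            s += (1.0 - self.decay) * p

    def write_back(self, params: list[np.ndarray]) -> None:
        if self.shadow is None or not self.started:
            return
        for p, s in zip(params, self.shadow):
            p[...] = s


def _generator_update(generator: MLP, g_opt, critic: MLP,
                      rng: np.random.Generator, batch_size: int,
                      noise_dim: int) -> float:
    z = rng.standard_normal((batch_size, noise_dim))
    fake, g_cache = generator.forward(z, want_cache=True)
    out, d_cache = critic.forward(fake, want_cache=True)
    # d(-mean D)/d fake
    _, _, grad_fake = critic.backward(
        d_cache, np.full((batch_size, 1), -1.0 / batch_size)
    )
    gw, gb, _ = generator.backward(g_cache, grad_fake)
    mlp_step(g_opt, generator, gw, gb)
    return float(-out.mean())


class LatentWGAN(BaseEstimator):
    """Scikit-learn-style WGAN-GP over latent vectors.

    Parameters mirror :class:`TrainConfig`; ``fit(X)`` pre-trains on the
    rows of ``X`` (one latent vector per row) and ``sample(n)`` draws new
    latent vectors from the trained generator.

    Fitted attributes: ``generator_``, ``critic_``, ``history_``,
    ``latent_dim_``, ``n_features_in_``.
    """

    def __init__(self, noise_dim: int = DEFAULT_NOISE_DIM,
                 gen_hidden: tuple[int, ...] = DEFAULT_GEN_HIDDEN,
                 critic_hidden: tuple[int, ...] = DEFAULT_CRITIC_HIDDEN,
                 epochs: int = 200, batch_size: int = 128,
                 learning_rate: float = 1e-3, gp_lambda: float = 10.0,
                 critic_steps: int = 5,
                 adam_betas: tuple[float, float] = (0.0, 0.9),
                 ema_decay: float = 0.995, lr_decay: bool = True,
                 random_state: int | None = None):
        self.noise_dim = noise_dim
        self.gen_hidden = gen_hidden
        self.critic_hidden = critic_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.gp_lambda = gp_lambda
        self.critic_steps = critic_steps
        self.adam_betas = adam_betas
        self.ema_decay = ema_decay
        self.lr_decay = lr_decay
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            gp_lambda=self.gp_lambda,
            critic_steps_per_gen_step=self.critic_steps,
            adam_betas=tuple(self.adam_betas),
            seed=0 if self.random_state is None else int(self.random_state),
            noise_dim=self.noise_dim,
            ema_decay=self.ema_decay,
            lr_decay=self.lr_decay,
        )

    def fit(self, X: np.ndarray, y=None) -> "LatentWGAN":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("latent matrix contains non-finite entries")
        self.n_features_in_ = X.shape[1]
        self.latent_dim_ = X.shape[1]
        cfg = self._config()
        seed_g, seed_d = derive_seeds(cfg.seed, 2)
        gen = MLP.build(generator_spec(cfg.noise_dim, self.latent_dim_,
                                       self.gen_hidden), seed_g)
        critic = MLP.build(critic_spec(self.latent_dim_, self.critic_hidden),
                           seed_d)
        self.generator_, self.critic_, self.history_ = pretrain(X, gen, critic, cfg)
        return self

    def sample(self, n_samples: int, random_state: int | None = None) -> np.ndarray:
        """Draw ``n_samples`` latent vectors from the trained generator."""
        if not hasattr(self, "generator_"):
            raise RuntimeError("LatentWGAN is not fitted")
        seed = self.random_state if random_state is None else random_state
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((int(n_samples), self.noise_dim))
        if n_samples == 0:
            return np.empty((0, self.latent_dim_))
        return self.generator_.forward(z)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def config_hash(obj) -> str:
    payload = json.dumps(asdict(obj) if hasattr(obj, "__dataclass_fields__")
                         else obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --- checkpoints ----------------------------------------------------------

def save_mlp(path: str | Path, mlp: MLP, opt=None, meta: dict | None = None) -> None:
    """Serialize an MLP (and optionally its Adam state) to a portable .npz."""
    arrays: dict[str, np.ndarray] = {}
    for k, (w, b) in enumerate(zip(mlp.weights, mlp.biases)):
        arrays[f"w{k}"] = w
        arrays[f"b{k}"] = b
    if opt is not None:
        for i, (m, v) in enumerate(zip(opt.m, opt.v)):
            arrays[f"adam_m{i}"] = m
            arrays[f"adam_v{i}"] = v
        arrays["adam_t"] = np.array([opt.t])
    header = {
        "widths": list(mlp.spec.widths),
        "hidden_activation": mlp.spec.hidden_activation,
        "frozen": list(mlp.frozen),
        "meta": meta or {},
    }
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **arrays)


def load_mlp(path: str | Path) -> tuple[MLP, dict]:
    """Bit-exact reload of :func:`save_mlp`; returns (mlp, header)."""
    data = np.load(Path(path))
    header = json.loads(bytes(data["header"].tobytes()).decode())
    spec = MLPSpec(tuple(header["widths"]), header["hidden_activation"])
    weights = [data[f"w{k}"] for k in range(spec.n_weight_layers)]
    biases = [data[f"b{k}"] for k in range(spec.n_weight_layers)]
    mlp = MLP(spec=spec, weights=weights, biases=biases,
              frozen=[bool(f) for f in header["frozen"]])
    return mlp, header
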
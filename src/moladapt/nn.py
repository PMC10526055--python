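"""Minimal NumPy MLPs with exact gradients for Wasserstein-GAN training.

The networks here are small (a few hundred thousand parameters at most), so
plain NumPy with hand-derived gradients is both fast enough on one CPU and
fully deterministic.  Three gradient routines are provided:

* ``backward`` — standard reverse-mode parameter/input gradients of a loss;
* ``input_gradient`` — per-sample gradient of a scalar-output critic with
  respect to its input (the ∇_x D(x) appearing in the gradient penalty);
* ``gradient_penalty_backward`` — parameter gradients of the penalty
  λ·mean((‖∇_x D(x)‖₂ − 1)²) itself.  For piecewise-linear activations
  (leaky ReLU) the activation slopes are locally constant, so the double
  backprop below is exact almost everywhere; bias gradients of the penalty
  vanish identically for the same reason.

Hidden activations are tanh (generator) or leaky ReLU with slope 0.2
(critic); output layers are always linear — the critic must be unbounded
and VAE latents are unbounded too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class MLPSpec:
    """Architecture: ``widths`` includes input and output widths."""

    widths: tuple[int, ...]
    hidden_activation: str = "leaky_relu"  # or "tanh"

    def __post_init__(self) -> None:
        if len(self.widths) < 2:
            raise ValueError("MLPSpec needs at least input and output widths")
        if any(w <= 0 for w in self.widths):
            raise ValueError(f"all widths must be positive: {self.widths}")
        if self.hidden_activation not in ("tanh", "leaky_relu"):
            raise ValueError(f"unknown activation {self.hidden_activation!r}")

    @property
    def n_weight_layers(self) -> int:
        return len(self.widths) - 1

    @property
    def n_params(self) -> int:
        return sum(
            (w_in + 1) * w_out for w_in, w_out in zip(self.widths, self.widths[1:])
        )


def _act(spec: MLPSpec, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Activation value and its derivative at pre-activation ``a``."""
    if spec.hidden_activation == "tanh":
        h = np.tanh(a)
        return h, 1.0 - h * h
    h = np.where(a > 0, a, LEAKY_SLOPE * a)
    return h, np.where(a > 0, 1.0, LEAKY_SLOPE)


@dataclass
class MLP:
    """Parameter container: weights[k] has shape (widths[k+1], widths[k])."""

    spec: MLPSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    frozen: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frozen:
            self.frozen = [False] * self.spec.n_weight_layers
        for k, (w_in, w_out) in enumerate(zip(self.spec.widths, self.spec.widths[1:])):
            if self.weights[k].shape != (w_out, w_in) or self.biases[k].shape != (w_out,):
                raise ValueError(f"layer {k} parameter shape inconsistent with spec")

    @classmethod
    def build(cls, spec: MLPSpec, seed: int) -> "MLP":
        """Fan-in-scaled Gaussian initialization, zero biases, reproducible."""
        rng = np.random.default_rng(seed)
        weights, biases = [], []
        for w_in, w_out in zip(spec.widths, spec.widths[1:]):
            weights.append(rng.standard_normal((w_out, w_in)) / np.sqrt(w_in))
            biases.append(np.zeros(w_out))
        return cls(spec=spec, weights=weights, biases=biases)

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    def copy(self) -> "MLP":
        return MLP(
            spec=self.spec,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            frozen=list(self.frozen),
        )

    def param_hash(self, layers: list[int] | None = None) -> str:
        """Hash of (a subset of) the parameters, for freeze-contract checks."""
        import hashlib

        h = hashlib.sha256()
        idx = range(self.spec.n_weight_layers) if layers is None else layers
        for k in idx:
            h.update(np.ascontiguousarray(self.weights[k]).tobytes())
            h.update(np.ascontiguousarray(self.biases[k]).tobytes())
        return h.hexdigest()

    # --- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Batched forward pass; ``x`` is (batch, widths[0])."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.spec.widths[0]:
            raise ValueError(
                f"input width {x.shape[1]} != expected {self.spec.widths[0]}"
            )
        hs = [x]  # post-activation values, hs[k] feeds weight layer k
        slopes: list[np.ndarray] = []  # activation derivatives per hidden layer
        h = x
        n_layers = self.spec.n_weight_layers
        for k in range(n_layers):
            a = h @ self.weights[k].T + self.biases[k]
            if k < n_layers - 1:
                h, s = _act(self.spec, a)
                hs.append(h)
                slopes.append(s)
            else:
                h = a  # linear output layer
        if want_cache:
            return h, {"hs": hs, "slopes": slopes}
        return h

    def backward(self, cache: dict, grad_out: np.ndarray):
        """Gradients of sum(grad_out * output) w.r.t. parameters and input.

        Returns ``(grad_weights, grad_biases, grad_input)``.
        """
        hs, slopes = cache["hs"], cache["slopes"]
        n_layers = self.spec.n_weight_layers
        gw = [None] * n_layers
        gb = [None] * n_layers
        delta = np.atleast_2d(np.asarray(grad_out, dtype=float))
        for k in range(n_layers - 1, -1, -1):
            gw[k] = delta.T @ hs[k]
            gb[k] = delta.sum(axis=0)
            grad_h = delta @ self.weights[k]
            if k > 0:
                delta = grad_h * slopes[k - 1]
        return gw, gb, grad_h

    def input_gradient(self, cache: dict) -> np.ndarray:
        """Per-sample ∇_x of a scalar-output network, shape (batch, widths[0])."""
        if self.spec.widths[-1] != 1:
            raise ValueError("input_gradient requires a scalar output")
        batch = cache["hs"][0].shape[0]
        _, _, gx = self.backward(cache, np.ones((batch, 1)))
        return gx

    def gradient_penalty_backward(self, cache: dict, gp_lambda: float):
        """Penalty value and its parameter gradients at the cached inputs.

        Computes P = gp_lambda * mean_i (‖g_i‖₂ − 1)² with
        g_i = ∇_x D(x_i), and dP/dW_k treating the piecewise-linear
        activation slopes as locally constant (exact a.e. for leaky ReLU).
        Bias gradients of P are identically zero in that regime.
        """
        if self.spec.widths[-1] != 1:
            raise ValueError("gradient penalty requires a scalar-output critic")
        slopes = cache["slopes"]
        n_layers = self.spec.n_weight_layers
        batch = cache["hs"][0].shape[0]

        # t-chain: t[k] = (transposed product of layers above k), per sample
        ts: list[np.ndarray | None] = [None] * (n_layers + 1)
        t = np.ones((batch, 1))
        ts[n_layers] = t
        for k in range(n_layers - 1, 0, -1):
            t = (t @ self.weights[k]) * slopes[k - 1]
            ts[k] = t
        g = ts[1] @ self.weights[0]  # (batch, d_in) = per-sample input gradient

        norms = np.linalg.norm(g, axis=1)
        penalty = gp_lambda * float(np.mean((norms - 1.0) ** 2))
        safe = np.maximum(norms, 1e-12)
        coeff = (2.0 * gp_lambda / batch) * (norms - 1.0) / safe
        u = coeff[:, None] * g  # dP/dg per sample

        # r-chain: push u forward through the linearized network
        rs = [u]
        r = u
        for j in range(1, n_layers):
            r = (r @ self.weights[j - 1].T) * slopes[j - 1]
            rs.append(r)

        gw = [ts[k + 1].T @ rs[k] for k in range(n_layers)]
        gb = [np.zeros_like(b) for b in self.biases]
        return penalty, gw, gb


class Adam:
    """Adam with per-layer freeze masks; state lives with the optimizer."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.0, 0.9), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list,
             update_mask: list[bool] | None = None) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if update_mask is not None and not update_mask[i]:
                continue
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def mlp_optimizer(mlp: MLP, lr: float, betas: tuple[float, float]) -> Adam:
    return Adam(mlp.weights + mlp.biases, lr=lr, betas=betas)


def mlp_step(opt: Adam, mlp: MLP, gw: list, gb: list) -> None:
    """Apply one Adam step to an MLP, honoring per-layer freeze flags."""
    mask = [not f for f in mlp.frozen] * 2
    opt.step(mlp.weights + mlp.biases, list(gw) + list(gb), update_mask=mask)
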
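"""ZINB autoencoder trained by explicit backpropagation.

A compact fully-connected autoencoder on the per-cell standardized
expression matrix. The decoder ends in three heads that parameterize a
zero-inflated negative binomial per matrix entry:

* ``pi``    — dropout probability, logistic head;
* ``mu``    — NB mean, ``size_factor * exp(raw)`` so depth differences are
  carried by the size factor rather than learned;
* ``theta`` — NB dispersion, softplus head, clamped away from 0 and inf.

Gradients of the ZINB negative log-likelihood with respect to the three head
pre-activations are derived analytically (see ``_zinb_head_grads``) and
propagated through the dense stack by hand; parameters are updated with
Adam. Everything is plain numpy, so a fixed seed gives bit-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit

from .errors import TrainingDivergedError
from .zinb import zinb_loss

__all__ = ["AEConfig", "ZINBParams", "ZINBAutoencoder", "pretrain"]

_CLAMP = 15.0  # bound on pre-exp / pre-softplus activations
_THETA_MIN, _THETA_MAX = 1e-4, 1e4
_PI_EPS = 1e-6


@dataclass
class AEConfig:
    """Autoencoder hyperparameters.

    Defaults follow the DCA-style recipe: a small symmetric bottleneck
    ([64, 32] encoder, 32-dimensional latent space), Adam at 1e-3, batch 256,
    long pretraining and a shorter GMM fine-tuning stage. ``variance_floor``
    bounds the mixture covariance eigenvalues away from zero.
    """

    encoder_sizes: list[int] = field(default_factory=lambda: [64, 32])
    latent_dim: int = 32
    pretrain_epochs: int = 300
    finetune_epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 256
    seed: int = 0
    variance_floor: float = 1e-4
    zinb_lambda: float = 0.0  # weight of the ZINB term during fine-tuning

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.pretrain_epochs < 1:
            raise ValueError("pretrain_epochs must be >= 1")
        if self.finetune_epochs < 0:
            raise ValueError("finetune_epochs must be >= 0")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("invalid optimizer settings")


@dataclass
class ZINBParams:
    """Per-entry ZINB parameters emitted by the decoder heads."""

    pi: np.ndarray
    mu: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("pi must lie in [0, 1]")
        if np.any(self.mu <= 0) or np.any(self.theta <= 0):
            raise ValueError("mu and theta must be positive")

    def loss(self, x: np.ndarray) -> float:
        return zinb_loss(x, self.pi, self.mu, self.theta)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class _Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _zinb_head_grads(
    x: np.ndarray, pi: np.ndarray, mu: np.ndarray, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic d(NLL)/d(pi), d(NLL)/d(mu), d(NLL)/d(theta), elementwise.

    For x = 0 the mixture weight A = pi + (1-pi) B with B = NB(0|mu,theta)
    couples all three parameters; for x > 0 only the NB branch contributes.
    """
    zero = x == 0
    log_b = theta * (np.log(theta) - np.log(theta + mu))
    b = np.exp(log_b)
    a_mix = pi + (1.0 - pi) * b
    a_mix = np.maximum(a_mix, 1e-300)

    g_pi = np.where(zero, -(1.0 - b) / a_mix, 1.0 / (1.0 - pi))

    nb_dmu = (x + theta) / (theta + mu) - x / np.maximum(mu, 1e-300)
    g_mu = np.where(zero, (1.0 - pi) * b / a_mix * theta / (theta + mu), nb_dmu)

    common = np.log(theta) - np.log(theta + mu) + 1.0 - theta / (theta + mu)
    nb_dth = -(digamma(x + theta) - digamma(theta) + common - x / (theta + mu))
    g_th = np.where(zero, -(1.0 - pi) * b / a_mix * common, nb_dth)
    return g_pi, g_mu, g_th


class ZINBAutoencoder:
    """Dense autoencoder with ZINB output heads and manual backprop."""

    def __init__(self, n_genes: int, cfg: AEConfig) -> None:
        self.cfg = cfg
        self.n_genes = n_genes
        rng = np.random.default_rng(cfg.seed)
        enc_dims = [n_genes, *cfg.encoder_sizes, cfg.latent_dim]
        dec_hidden = list(reversed(cfg.encoder_sizes))
        dec_dims = [cfg.latent_dim, *dec_hidden]
        self.enc_W = [_glorot(rng, a, b) for a, b in zip(enc_dims, enc_dims[1:])]
        self.enc_b = [np.zeros(b) for b in enc_dims[1:]]
        self.dec_W = [_glorot(rng, a, b) for a, b in zip(dec_dims, dec_dims[1:])]
        self.dec_b = [np.zeros(b) for b in dec_dims[1:]]
        last = dec_dims[-1]
        self.head_W = {h: _glorot(rng, last, n_genes) for h in ("pi", "mu", "theta")}
        self.head_b = {h: np.zeros(n_genes) for h in ("pi", "mu", "theta")}

    # ---- parameter bookkeeping -------------------------------------------
    def _all_params(self) -> list[np.ndarray]:
        return (
            self.enc_W
            + self.enc_b
            + self.dec_W
            + self.dec_b
            + [self.head_W[h] for h in ("pi", "mu", "theta")]
            + [self.head_b[h] for h in ("pi", "mu", "theta")]
        )

    def encoder_params(self) -> list[np.ndarray]:
        return self.enc_W + self.enc_b

    # ---- forward ----------------------------------------------------------
    def encode(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        h = x
        acts = [x]
        for i, (w, b) in enumerate(zip(self.enc_W, self.enc_b)):
            pre = h @ w + b
            h = np.maximum(pre, 0.0) if i < len(self.enc_W) - 1 else pre
            acts.append(h)
        if cache is not None:
            cache["enc_acts"] = acts
        return h

    def decode(
        self, z: np.ndarray, size_factors: np.ndarray, cache: dict | None = None
    ) -> ZINBParams:
        h = z
        acts = [z]
        for w, b in zip(self.dec_W, self.dec_b):
            h = np.maximum(h @ w + b, 0.0)
            acts.append(h)
        a_pi = h @ self.head_W["pi"] + self.head_b["pi"]
        a_mu = h @ self.head_W["mu"] + self.head_b["mu"]
        a_th = h @ self.head_W["theta"] + self.head_b["theta"]
        mu_clip = np.clip(a_mu, -_CLAMP, _CLAMP)
        th_clip = np.clip(a_th, -_CLAMP, _CLAMP)
        pi = np.clip(expit(a_pi), _PI_EPS, 1.0 - _PI_EPS)
        mu = size_factors[:, None] * np.exp(mu_clip)
        theta_raw = _softplus(th_clip)
        theta = np.clip(theta_raw, _THETA_MIN, _THETA_MAX)
        if cache is not None:
            cache.update(
                dec_acts=acts,
                a_pi=a_pi,
                mu_unclipped=a_mu,
                th_unclipped=a_th,
                mu_clip_mask=(np.abs(a_mu) < _CLAMP),
                th_clip_mask=(np.abs(a_th) < _CLAMP)
                & (theta_raw > _THETA_MIN)
                & (theta_raw < _THETA_MAX),
                pi=pi,
                mu=mu,
                theta=theta,
            )
        return ZINBParams(pi, mu, theta)

    # ---- backward ---------------------------------------------------------
    def _backprop_dense(
        self,
        delta: np.ndarray,
        acts: list[np.ndarray],
        weights: list[np.ndarray],
        last_linear: bool,
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Backprop *delta* (grad wrt the stack's output) through a dense stack.

        Returns (weight grads, bias grads, grad wrt the stack's input).
        ReLU on every layer except, when *last_linear*, the final one.
        """
        gw = [np.zeros_like(w) for w in weights]
        gb = [np.zeros_like(w[0]) for w in weights]
        for i in range(len(weights) - 1, -1, -1):
            if not (last_linear and i == len(weights) - 1):
                delta = delta * (acts[i + 1] > 0)
            gw[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            delta = delta @ weights[i].T
        return gw, gb, delta

    def backward_zinb(
        self, x_counts: np.ndarray, cache: dict, scale: float
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients of scale * sum(-log ZINB) for every parameter.

        Returns (grads aligned with ``_all_params()``, grad wrt the scaled
        input's latent code) so callers may reuse the decoder path while
        freezing its parameters.
        """
        pi, mu, theta = cache["pi"], cache["mu"], cache["theta"]
        g_pi, g_mu, g_th = _zinb_head_grads(x_counts, pi, mu, theta)
        d_api = g_pi * pi * (1.0 - pi) * scale
        d_amu = g_mu * mu * cache["mu_clip_mask"] * scale
        d_ath = g_th * expit(cache["th_unclipped"]) * cache["th_clip_mask"] * scale

        h_last = cache["dec_acts"][-1]
        gw_heads, gb_heads = {}, {}
        delta_h = np.zeros_like(h_last)
        for name, d_a in (("pi", d_api), ("mu", d_amu), ("theta", d_ath)):
            gw_heads[name] = h_last.T @ d_a
            gb_heads[name] = d_a.sum(axis=0)
            delta_h = delta_h + d_a @ self.head_W[name].T

        gw_dec, gb_dec, delta_z = self._backprop_dense(
            delta_h, cache["dec_acts"], self.dec_W, last_linear=False
        )
        gw_enc, gb_enc, _ = self._backprop_dense(
            delta_z, cache["enc_acts"], self.enc_W, last_linear=True
        )
        grads = (
            gw_enc
            + gb_enc
            + gw_dec
            + gb_dec
            + [gw_heads[h] for h in ("pi", "mu", "theta")]
            + [gb_heads[h] for h in ("pi", "mu", "theta")]
        )
        return grads, delta_z

    def encoder_grads_from_latent(
        self, delta_z: np.ndarray, cache: dict
    ) -> list[np.ndarray]:
        """Backprop a latent-space gradient through the encoder only."""
        gw_enc, gb_enc, _ = self._backprop_dense(
            delta_z, cache["enc_acts"], self.enc_W, last_linear=True
        )
        return gw_enc + gb_enc


def pretrain(
    counts: np.ndarray,
    scaled: np.ndarray,
    cfg: AEConfig,
    size_factors: np.ndarray | None = None,
) -> tuple[ZINBAutoencoder, np.ndarray, list[float]]:
    """Stage 1: train the autoencoder on the ZINB reconstruction loss.

    *counts* are the raw counts (targets of the likelihood), *scaled* the
    standardized log-normalized matrix fed to the encoder. Returns the
    trained model, the latent encodings and the per-epoch mean losses
    (per-entry average, epoch-weighted).
    """
    counts = np.asarray(counts, dtype=float)
    scaled = np.asarray(scaled, dtype=float)
    n, g = counts.shape
    if scaled.shape != (n, g):
        raise ValueError("counts and scaled matrices must share a shape")
    if size_factors is None:
        totals = counts.sum(axis=1)
        size_factors = totals / np.median(totals)
    model = ZINBAutoencoder(g, cfg)
    params = model._all_params()
    opt = _Adam(params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    epoch_losses: list[float] = []
    for epoch in range(cfg.pretrain_epochs):
        order = rng.permutation(n)
        total_nll = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            cache: dict = {}
            z = model.encode(scaled[idx], cache)
            pars = model.decode(z, size_factors[idx], cache)
            batch_nll = pars.loss(counts[idx])
            if not np.isfinite(batch_nll):
                raise TrainingDivergedError(
                    f"non-finite ZINB loss at epoch {epoch + 1}"
                )
            total_nll += batch_nll
            grads, _ = model.backward_zinb(
                counts[idx], cache, scale=1.0 / (idx.size * g)
            )
            opt.step(params, grads)
        epoch_losses.append(total_nll / (n * g))
    latent = model.encode(scaled)
    return model, latent, epoch_losses
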
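"""Gaussian mixture machinery for the fine-tuning stage.

The latent representation of each cluster c is modeled as a Gaussian with
mixing weight pi_c, mean mu_c and diagonal covariance Sigma_c (eigenvalues
floored). The fine-tuning loss is the mixture negative log-likelihood

    L_GMM = sum_i -ln sum_c pi_c N(z_i; mu_c, Sigma_c)

minimized jointly over the encoder weights and the mixture parameters by
gradient descent: weights through a softmax parameterization, variances
through ``floor + exp(v)`` so the floor is respected by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .louvain import Partition
from .nn import AEConfig, ZINBAutoencoder, _Adam
from .errors import TrainingDivergedError

__all__ = ["GMMState", "init_gmm", "gmm_nll", "soft_assign", "finetune"]


@dataclass
class GMMState:
    """Mixture weights, means and diagonal covariances (one row per cluster)."""

    weights: np.ndarray  # (K,), sums to 1
    means: np.ndarray  # (K, d)
    variances: np.ndarray  # (K, d) diagonal of Sigma_c

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def covariances(self) -> np.ndarray:
        """Full (K, d, d) diagonal covariance matrices."""
        return np.stack([np.diag(v) for v in self.variances])


def _log_gauss_diag(x: np.ndarray, state: GMMState) -> np.ndarray:
    """(n, K) log N(x_i; mu_c, diag(var_c)) with the standard normalizer."""
    x = np.atleast_2d(x)
    d = state.dim
    diff = x[:, None, :] - state.means[None, :, :]  # (n, K, d)
    maha = np.sum(diff * diff / state.variances[None, :, :], axis=2)
    log_det = np.sum(np.log(state.variances), axis=1)  # (K,)
    return -0.5 * (d * np.log(2.0 * np.pi) + log_det[None, :] + maha)


def init_gmm(latent: np.ndarray, p: Partition, variance_floor: float = 1e-4) -> GMMState:
    """Moment-match one Gaussian per community of the latent-space partition.

    Means are per-cluster centroids, covariances the per-cluster diagonal
    sample covariances floored at *variance_floor* (clusters with fewer than
    2 members fall back to floor * identity), weights the cluster
    frequencies.
    """
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    labels = np.asarray(p.labels)
    if labels.shape[0] != latent.shape[0]:
        raise ValueError("partition and latent matrix disagree on n")
    k = int(labels.max()) + 1
    d = latent.shape[1]
    weights = np.zeros(k)
    means = np.zeros((k, d))
    variances = np.full((k, d), variance_floor)
    for c in range(k):
        members = latent[labels == c]
        weights[c] = members.shape[0] / latent.shape[0]
        means[c] = members.mean(axis=0)
        if members.shape[0] >= 2:
            variances[c] = np.maximum(members.var(axis=0, ddof=0), variance_floor)
    return GMMState(weights, means, variances)


def gmm_nll(latent: np.ndarray, state: GMMState) -> float:
    """Mixture negative log-likelihood, evaluated with log-sum-exp."""
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    if latent.shape[1] != state.dim:
        raise ValueError("latent dimension does not match the mixture")
    log_prob = _log_gauss_diag(latent, state) + np.log(state.weights)[None, :]
    return float(-np.sum(logsumexp(log_prob, axis=1)))


def soft_assign(latent: np.ndarray, state: GMMState) -> np.ndarray:
    """Responsibilities r_ic = pi_c N(z_i|c) / sum_c' pi_c' N(z_i|c').

    Computed in log space, so heavily separated components never produce
    NaN rows; every row sums to 1.
    """
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    log_prob = _log_gauss_diag(latent, state) + np.log(state.weights)[None, :]
    log_r = log_prob - logsumexp(log_prob, axis=1, keepdims=True)
    return np.exp(log_r)


def _responsibilities_and_nll(
    z: np.ndarray, log_w: np.ndarray, means: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    d = means.shape[1]
    diff = z[:, None, :] - means[None, :, :]
    maha = np.sum(diff * diff / variances[None, :, :], axis=2)
    log_det = np.sum(np.log(variances), axis=1)
    log_gauss = -0.5 * (d * np.log(2.0 * np.pi) + log_det[None, :] + maha)
    log_prob = log_gauss + log_w[None, :]
    log_norm = logsumexp(log_prob, axis=1, keepdims=True)
    resp = np.exp(log_prob - log_norm)
    return resp, float(-np.sum(log_norm)), diff


def finetune(
    model: ZINBAutoencoder,
    counts: np.ndarray,
    scaled: np.ndarray,
    gmm0: GMMState,
    cfg: AEConfig,
    size_factors: np.ndarray | None = None,
) -> tuple[ZINBAutoencoder, GMMState, np.ndarray, list[float]]:
    """Stage 2: jointly optimize encoder and mixture on L_GMM.

    The decoder is frozen; mixture weights are parameterized through a
    softmax and variances through ``floor + exp(v)``, so the probability
    simplex and the variance floor hold at every step. When
    ``cfg.zinb_lambda > 0`` the frozen decoder's ZINB loss is added as a
    regularizer (gradients flow through it into the encoder only). Returns
    the updated model, mixture, latent matrix and per-epoch L_GMM values
    (per-cell mean). With ``finetune_epochs == 0`` the inputs are returned
    unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    scaled = np.asarray(scaled, dtype=float)
    n, g = scaled.shape
    if size_factors is None:
        totals = counts.sum(axis=1)
        size_factors = totals / np.median(totals)
    if cfg.finetune_epochs == 0:
        return model, gmm0, model.encode(scaled), []

    floor = cfg.variance_floor
    log_w = np.log(np.maximum(gmm0.weights, 1e-12))  # softmax logits
    means = gmm0.means.copy()
    v_raw = np.log(np.maximum(gmm0.variances - floor, 1e-12))

    enc_params = model.encoder_params()
    mix_params = [log_w, means, v_raw]
    opt_enc = _Adam(enc_params, cfg.learning_rate)
    opt_mix = _Adam(mix_params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 2)

    epoch_nll: list[float] = []
    for epoch in range(cfg.finetune_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            cache: dict = {}
            z = model.encode(scaled[idx], cache)
            weights = softmax(log_w - log_w.max())
            variances = floor + np.exp(v_raw)
            resp, nll, diff = _responsibilities_and_nll(
                z, np.log(weights), means, variances
            )
            if not np.isfinite(nll):
                raise TrainingDivergedError(
                    f"non-finite GMM loss at fine-tuning epoch {epoch + 1}"
                )
            total += nll
            m = idx.size
            scale = 1.0 / m
            # d NLL / d z_i = sum_c r_ic Sigma_c^{-1} (z_i - mu_c)
            weighted = resp[:, :, None] * diff / variances[None, :, :]
            delta_z = weighted.sum(axis=1) * scale
            # mixture-parameter gradients
            g_means = -weighted.sum(axis=0) * scale
            g_vraw = (
                0.5
                * np.sum(
                    resp[:, :, None] * (1.0 / variances[None, :, :])
                    - weighted * diff / variances[None, :, :],
                    axis=0,
                )
                * np.exp(v_raw)
                * scale
            )
            g_logw = (weights * m - resp.sum(axis=0)) * scale

            enc_grads = model.encoder_grads_from_latent(delta_z, cache)
            if cfg.zinb_lambda > 0:
                model.decode(z, size_factors[idx], cache)
                zgrads, _ = model.backward_zinb(
                    counts[idx], cache, scale=cfg.zinb_lambda / (m * g)
                )
                n_enc = len(enc_grads)
                enc_grads = [a + b for a, b in zip(enc_grads, zgrads[:n_enc])]
            opt_enc.step(enc_params, enc_grads)
            opt_mix.step(mix_params, [g_logw, g_means, g_vraw])
        epoch_nll.append(total / n)

    weights = softmax(log_w - log_w.max())
    variances = floor + np.exp(v_raw)
    state = GMMState(weights / weights.sum(), means, variances)
    return model, state, model.encode(scaled), epoch_nll
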
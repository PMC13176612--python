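"""scikit-learn style estimators for the two clustering algorithms.

:class:`KMSTCluster` — normalize, select highly variable genes, correlate
cells, build the k-MST graph and partition it with Louvain.

:class:`AEGMMCluster` — standardize, pretrain a ZINB autoencoder, estimate
the number of clusters by running the k-MST algorithm on the latent space,
then fine-tune encoder + Gaussian mixture on the GMM likelihood for soft
assignments.

Both follow the sklearn contract (``fit`` / ``fit_predict``, ``get_params``
/ ``set_params``, trailing-underscore fitted attributes) and therefore
compose with sklearn model selection; the module-level ``kmst_cluster`` and
``aegmm_cluster`` functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import DegenerateInputError
from .gmm import GMMState, finetune, gmm_nll, init_gmm, soft_assign
from .graph import (
    KMSTConfig,
    build_kmst,
    pearson_similarity,
    similarity_to_distance,
)
from .io import CountMatrix
from .louvain import Partition, louvain, modularity
from .nn import AEConfig, pretrain
from .preprocess import (
    fit_variance_trend,
    normalize,
    select_hvg,
    standard_scale,
)

__all__ = [
    "ClusteringResult",
    "KMSTCluster",
    "AEGMMCluster",
    "estimate_n_clusters",
    "kmst_cluster",
    "aegmm_cluster",
]


@dataclass
class ClusteringResult:
    """Hard labels plus whatever else the algorithm produced."""

    labels: np.ndarray
    n_clusters: int
    responsibilities: np.ndarray | None = None
    objective: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.responsibilities is not None:
            rows = self.responsibilities.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > 1e-9):
                raise ValueError("responsibility rows must sum to 1")


def _as_count_matrix(X) -> CountMatrix:
    if isinstance(X, CountMatrix):
        return X
    if sp.issparse(X):
        return CountMatrix(X.tocsr())
    return CountMatrix(sp.csr_matrix(np.asarray(X)))


def _latent_partition(latent: np.ndarray, kcfg: KMSTConfig) -> Partition:
    """k-MST + Louvain on row vectors; collapses the all-duplicates case."""
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    n = latent.shape[0]
    if n < 2:
        return Partition(np.zeros(max(n, 1), dtype=int))
    sim = pearson_similarity(latent)
    off = sim.values[~np.eye(n, dtype=bool)]
    if np.all(off >= 1.0 - 1e-12):  # all cells correlation-1 duplicates
        return Partition(np.zeros(n, dtype=int))
    dist = similarity_to_distance(sim)
    graph, _ = build_kmst(dist, kcfg.resolve_k(n))
    return louvain(graph, seed=kcfg.seed, resolution=kcfg.louvain_resolution)


def estimate_n_clusters(latent: np.ndarray, kcfg: KMSTConfig | None = None) -> int:
    """Number of communities the k-MST graph of the latent space supports."""
    kcfg = kcfg or KMSTConfig()
    return _latent_partition(latent, kcfg).n_communities


class KMSTCluster(BaseEstimator, ClusterMixin):
    """Graph-based clustering: correlations -> k-MST graph -> Louvain.

    Parameters
    ----------
    n_hvg : int
        Genes kept by the mean-variance-trend selection (top deviations).
    k : int or 'auto'
        Spanning-tree iterations; 'auto' uses ceil(ln n).
    seed : int
        Louvain node-order seed.
    resolution : float
        Louvain resolution.
    L : float or None
        Normalization depth; None = median per-cell total.

    Attributes
    ----------
    labels_ : (n,) cluster label per cell
    n_clusters_ : number of communities found
    modularity_ : modularity of the returned partition on the k-MST graph
    graph_ : the similarity-weighted k-MST union graph
    hvg_indices_ : indices of the genes used
    """

    def __init__(self, n_hvg: int = 5000, k: int | str = "auto", seed: int = 0,
                 resolution: float = 1.0, L: float | None = None):
        self.n_hvg = n_hvg
        self.k = k
        self.seed = seed
        self.resolution = resolution
        self.L = L

    def fit(self, X, y=None):
        counts = _as_count_matrix(X)
        nm = normalize(counts, L=self.L)
        try:
            trend = fit_variance_trend(nm)
            hvg = select_hvg(nm, trend, self.n_hvg)
            self.trend_ = trend
        except DegenerateInputError:
            # toy inputs with too few variable genes: keep everything
            hvg = np.arange(nm.n_genes)
            self.trend_ = None
        self.hvg_indices_ = hvg
        expr = nm.values[:, hvg]

        kcfg = KMSTConfig(k=self.k, seed=self.seed, louvain_resolution=self.resolution)
        n = expr.shape[0]
        sim = pearson_similarity(expr)
        off = sim.values[~np.eye(n, dtype=bool)]
        if np.all(off >= 1.0 - 1e-12):
            part = Partition(np.zeros(n, dtype=int))
            graph, _ = build_kmst(similarity_to_distance(sim), 1)
        else:
            dist = similarity_to_distance(sim)
            graph, self.trees_ = build_kmst(dist, kcfg.resolve_k(n))
            part = louvain(graph, seed=self.seed, resolution=self.resolution)
        self.graph_ = graph
        self.labels_ = part.labels
        self.n_clusters_ = part.n_communities
        self.modularity_ = modularity(graph, part)
        return self

    def result_(self) -> ClusteringResult:
        return ClusteringResult(self.labels_, self.n_clusters_, None, self.modularity_)


class AEGMMCluster(BaseEstimator, ClusterMixin):
    """Two-stage deep clustering: ZINB pretraining, then GMM fine-tuning.

    Stage 1 trains the autoencoder on the zero-inflated negative binomial
    reconstruction likelihood of the raw counts. The cluster count is then
    estimated by running the k-MST + Louvain procedure on the latent space,
    a Gaussian mixture is moment-matched to those communities, and stage 2
    jointly refines encoder and mixture on the mixture likelihood. Soft
    assignments (responsibilities) come from the final mixture.

    Attributes
    ----------
    labels_, n_clusters_, responsibilities_ : clustering outputs
    init_labels_ : latent-space k-MST labels before fine-tuning
    latent_ : final latent encodings
    nll_ : final GMM negative log-likelihood (total over cells)
    pretrain_losses_, finetune_losses_ : per-epoch training curves
    """

    def __init__(self, encoder_sizes=(64, 32), latent_dim: int = 32,
                 pretrain_epochs: int = 300, finetune_epochs: int = 100,
                 learning_rate: float = 1e-3, batch_size: int = 256,
                 seed: int = 0, variance_floor: float = 1e-4,
                 zinb_lambda: float = 0.0, k: int | str = "auto",
                 resolution: float = 1.0, L: float | None = None):
        self.encoder_sizes = encoder_sizes
        self.latent_dim = latent_dim
        self.pretrain_epochs = pretrain_epochs
        self.finetune_epochs = finetune_epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.variance_floor = variance_floor
        self.zinb_lambda = zinb_lambda
        self.k = k
        self.resolution = resolution
        self.L = L

    def _configs(self) -> tuple[AEConfig, KMSTConfig]:
        ae = AEConfig(
            encoder_sizes=list(self.encoder_sizes),
            latent_dim=self.latent_dim,
            pretrain_epochs=self.pretrain_epochs,
            finetune_epochs=self.finetune_epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.seed,
            variance_floor=self.variance_floor,
            zinb_lambda=self.zinb_lambda,
        )
        kcfg = KMSTConfig(k=self.k, seed=self.seed, louvain_resolution=self.resolution)
        return ae, kcfg

    def fit(self, X, y=None):
        counts = _as_count_matrix(X)
        ae_cfg, kcfg = self._configs()
        nm = normalize(counts, L=self.L)
        scaled = standard_scale(nm)
        raw = counts.toarray().astype(float)

        model, latent, self.pretrain_losses_ = pretrain(
            raw, scaled, ae_cfg, size_factors=nm.size_factors
        )
        part = _latent_partition(latent, kcfg)
        self.init_labels_ = part.labels
        self.n_clusters_ = part.n_communities
        gmm0 = init_gmm(latent, part, ae_cfg.variance_floor)

        model, gmm, latent, self.finetune_losses_ = finetune(
            model, raw, scaled, gmm0, ae_cfg, size_factors=nm.size_factors
        )
        self.model_ = model
        self.gmm_ = gmm
        self.latent_ = latent
        resp = soft_assign(latent, gmm)
        self.responsibilities_ = resp
        self.labels_ = np.argmax(resp, axis=1)  # argmax ties -> lowest index
        self.nll_ = gmm_nll(latent, gmm)
        return self

    def result_(self) -> ClusteringResult:
        return ClusteringResult(
            self.labels_, self.n_clusters_, self.responsibilities_, self.nll_
        )


def kmst_cluster(counts, kcfg: KMSTConfig | None = None, n_hvg: int = 5000,
                 L: float | None = None) -> ClusteringResult:
    """Functional wrapper over :class:`KMSTCluster`."""
    kcfg = kcfg or KMSTConfig()
    est = KMSTCluster(
        n_hvg=n_hvg, k=kcfg.k, seed=kcfg.seed,
        resolution=kcfg.louvain_resolution, L=L,
    ).fit(counts)
    return est.result_()


def aegmm_cluster(counts, cfg: AEConfig | None = None,
                  kcfg: KMSTConfig | None = None) -> ClusteringResult:
    """Functional wrapper over :class:`AEGMMCluster`."""
    cfg = cfg or AEConfig()
    kcfg = kcfg or KMSTConfig()
    est = AEGMMCluster(
        encoder_sizes=cfg.encoder_sizes, latent_dim=cfg.latent_dim,
        pretrain_epochs=cfg.pretrain_epochs, finetune_epochs=cfg.finetune_epochs,
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        seed=cfg.seed, variance_floor=cfg.variance_floor,
        zinb_lambda=cfg.zinb_lambda, k=kcfg.k,
        resolution=kcfg.louvain_resolution,
    ).fit(counts)
    return est.result_()
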
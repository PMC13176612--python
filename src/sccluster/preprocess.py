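"""QC filtering, normalization and highly-variable-gene selection.

The preprocessing chain mirrors the standard scRNA-seq recipe: cell-level QC
(mitochondrial fraction, expressed-gene bounds), an optional minimal gene
filter, total-count normalization to the median library size followed by
log1p, a parametric mean-variance trend fit, and selection of the genes with
the largest upward deviation from that trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import curve_fit

from .errors import (
    ConstantRowError,
    DegenerateInputError,
    EmptyResultError,
    ZeroTotalCountError,
)
from .io import CountMatrix

__all__ = [
    "QCConfig",
    "NormalizedMatrix",
    "TrendFit",
    "filter_cells",
    "filter_genes",
    "normalize",
    "fit_variance_trend",
    "select_hvg",
    "standard_scale",
]


@dataclass
class QCConfig:
    """Cell-level quality-control thresholds.

    Defaults follow common droplet-data practice: drop cells whose
    mitochondrial reads exceed 5% of the library or that express fewer than
    100 or more than 10,000 genes.
    """

    max_mito_fraction: float = 0.05
    min_genes_per_cell: int = 100
    max_genes_per_cell: int = 10_000
    mito_gene_prefix: str = "MT-"
    excluded_barcodes: set[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if not 0 <= self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValueError(
                "need 0 <= min_genes_per_cell < max_genes_per_cell"
            )


@dataclass
class NormalizedMatrix:
    """Log-scaled, depth-normalized expression (cells x genes).

    ``values`` holds ``log1p(count / size_factor)`` where
    ``size_factor = cell total / L`` and ``L`` defaults to the median raw
    per-cell total, so every cell's pre-log total equals ``L``.
    """

    values: np.ndarray
    size_factors: np.ndarray
    L: float
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def pre_log(self) -> np.ndarray:
        """The depth-scaled counts before the log transform."""
        return np.expm1(self.values)

    def subset_genes(self, genes) -> "NormalizedMatrix":
        genes = np.asarray(genes)
        return NormalizedMatrix(
            self.values[:, genes],
            self.size_factors,
            self.L,
            self.cell_ids,
            [self.gene_ids[j] for j in genes] if self.gene_ids else [],
        )


@dataclass
class TrendFit:
    """Fitted mean-variance trend sigma^2 = a * mu / (mu^p + b).

    ``per_gene_deviation`` is observed minus expected variance; genes above
    the curve (positive deviation) are the highly-variable candidates.
    """

    a: float
    b: float
    exponent: float
    per_gene_mean: np.ndarray
    per_gene_variance: np.ndarray
    per_gene_expected_variance: np.ndarray
    per_gene_deviation: np.ndarray

    def expected_variance(self, mean: np.ndarray) -> np.ndarray:
        return _trend_curve(np.asarray(mean, dtype=float), self.a, self.b, self.exponent)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "exponent": self.exponent}


def _expressed_genes_per_cell(values: sp.csr_matrix) -> np.ndarray:
    return np.asarray((values > 0).sum(axis=1)).ravel()


def filter_cells(m: CountMatrix, cfg: QCConfig) -> CountMatrix:
    """Keep cells passing the mitochondrial, expressed-gene and barcode filters.

    A cell survives iff ``min_genes <= # expressed genes <= max_genes``, its
    mitochondrial count fraction is at most ``max_mito_fraction`` and its
    barcode is not excluded. The gene set is unchanged.
    """
    n_expressed = _expressed_genes_per_cell(m.values)
    totals = np.asarray(m.values.sum(axis=1)).ravel().astype(float)
    mito_mask = np.array(
        [g.startswith(cfg.mito_gene_prefix) for g in m.gene_ids], dtype=bool
    )
    if mito_mask.any():
        mito_counts = np.asarray(m.values[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    keep = (
        (n_expressed >= cfg.min_genes_per_cell)
        & (n_expressed <= cfg.max_genes_per_cell)
        & (mito_frac <= cfg.max_mito_fraction)
    )
    if cfg.excluded_barcodes:
        keep &= np.array([c not in cfg.excluded_barcodes for c in m.cell_ids])
    if not keep.any():
        raise EmptyResultError("QC filtering removed every cell")
    return m.subset(cells=np.flatnonzero(keep))


def filter_genes(m: CountMatrix, min_cells_expressing: int = 3) -> CountMatrix:
    """Keep genes expressed (count > 0) in at least *min_cells_expressing* cells."""
    if min_cells_expressing < 0:
        raise ValueError("min_cells_expressing must be >= 0")
    if min_cells_expressing == 0:
        return m
    n_cells_expr = np.asarray((m.values > 0).sum(axis=0)).ravel()
    keep = n_cells_expr >= min_cells_expressing
    if not keep.any():
        raise EmptyResultError("gene filtering removed every gene")
    return m.subset(genes=np.flatnonzero(keep))


def normalize(m: CountMatrix, L: float | None = None) -> NormalizedMatrix:
    """Total-count normalize each cell to depth ``L`` and log1p-transform.

    ``L`` defaults to the median raw per-cell total; the per-cell size factor
    is ``total_i / L`` so that every cell's scaled total equals ``L`` before
    the log.
    """
    totals = np.asarray(m.values.sum(axis=1)).ravel().astype(float)
    if np.any(totals <= 0):
        bad = m.cell_ids[int(np.argmin(totals))]
        raise ZeroTotalCountError(f"cell {bad!r} has zero total counts")
    if L is None:
        L = float(np.median(totals))
    if L <= 0:
        raise ValueError("L must be positive")
    size_factors = totals / L
    scaled = m.toarray().astype(float) / size_factors[:, None]
    return NormalizedMatrix(
        np.log1p(scaled), size_factors, L, list(m.cell_ids), list(m.gene_ids)
    )


def _trend_curve(mu: np.ndarray, a: float, b: float, p: float) -> np.ndarray:
    return a * mu / (np.power(np.maximum(mu, 0.0), p) + b)


def fit_variance_trend(nm: NormalizedMatrix) -> TrendFit:
    """Fit the mean-variance trend sigma^2 = a*mu/(mu^p + b) across genes.

    Least squares on the per-gene (mean, variance) points of the
    log-normalized matrix; a, b bounded below at 1e-8, the exponent p in
    (0, 10], initialized at 1. Genes with zero variance are excluded from the
    fit but still receive a deviation (their observed variance, zero, minus
    the curve's expectation).
    """
    mean = nm.values.mean(axis=0)
    var = nm.values.var(axis=0, ddof=1) if nm.n_cells > 1 else np.zeros(nm.n_genes)
    usable = (var > 0) & (mean > 0)
    if usable.sum() < 3:
        raise DegenerateInputError(
            "need at least 3 genes with positive mean and variance to fit the trend"
        )
    mu_fit, var_fit = mean[usable], var[usable]
    a0 = max(float(var_fit.max()), 1e-3)
    try:
        popt, _ = curve_fit(
            _trend_curve,
            mu_fit,
            var_fit,
            p0=(a0, 1.0, 1.0),
            bounds=([1e-8, 1e-8, 1e-8], [np.inf, np.inf, 10.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise DegenerateInputError(f"variance-trend fit failed: {exc}") from exc
    a, b, p = (float(v) for v in popt)
    expected = _trend_curve(mean, a, b, p)
    deviation = var - expected
    return TrendFit(a, b, p, mean, var, expected, deviation)


def select_hvg(nm: NormalizedMatrix, fit: TrendFit, n_genes: int = 5000) -> np.ndarray:
    """Indices of the top *n_genes* genes by decreasing deviation from the trend.

    Ties are broken by ascending gene index for determinism; if *n_genes*
    exceeds the gene count, all genes are returned (still deviation-sorted).
    """
    if fit.per_gene_deviation.shape[0] != nm.n_genes:
        raise ValueError("trend fit was computed on a different gene set")
    order = np.lexsort((np.arange(nm.n_genes), -fit.per_gene_deviation))
    return order[: min(n_genes, nm.n_genes)]


def standard_scale(nm: NormalizedMatrix | np.ndarray, axis: str = "cells") -> np.ndarray:
    """Center and scale to unit population standard deviation.

    By default each cell (row) is scaled to mean 0, sd 1, matching the
    scDCC-style per-cell scaler; ``axis='genes'`` scales columns instead.
    """
    x = nm.values if isinstance(nm, NormalizedMatrix) else np.asarray(nm, dtype=float)
    ax = 1 if axis == "cells" else 0
    mean = x.mean(axis=ax, keepdims=True)
    sd = x.std(axis=ax, keepdims=True)  # population sd (ddof=0)
    if np.any(sd == 0):
        which = "cell" if ax == 1 else "gene"
        idx = int(np.argmin(sd.ravel()))
        raise ConstantRowError(f"{which} {idx} is constant and cannot be scaled")
    return (x - mean) / sd
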
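"""Supervised clustering evaluation and reference-based cell annotation.

NMI (arithmetic-mean normalization) and ARI are delegated to scikit-learn;
clustering accuracy is the fraction of cells matched under an optimal
one-to-one assignment between predicted and true clusters, solved on the
contingency table with the Hungarian algorithm (rectangular when cluster
counts differ; unmatched predicted clusters contribute nothing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .errors import NoSharedGenesError

__all__ = [
    "ReferenceProfiles",
    "clustering_accuracy",
    "nmi",
    "ari",
    "reference_annotate",
]

logger = logging.getLogger(__name__)


@dataclass
class ReferenceProfiles:
    """Average expression per cell type (types x genes)."""

    matrix: np.ndarray
    type_names: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape != (len(self.type_names), len(self.gene_ids)):
            raise ValueError("profile matrix shape does not match names")

    @classmethod
    def from_csv(cls, path: str) -> "ReferenceProfiles":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), [str(t) for t in df.index], [str(g) for g in df.columns])


def _check_lengths(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape[0] != pred.shape[0]:
        raise ValueError(
            f"label vectors differ in length ({truth.shape[0]} vs {pred.shape[0]})"
        )
    return truth, pred


def clustering_accuracy(truth, pred) -> float:
    """Best-match accuracy: optimal one-to-one cluster correspondence.

    Maximizes the matched-cell count over injective maps between predicted
    and true labels (linear assignment on the contingency table) and divides
    by n. Invariant to relabeling of either side; 1.0 iff the partitions are
    identical up to a bijection.
    """
    truth, pred = _check_lengths(truth, pred)
    cont = contingency_matrix(truth, pred)
    row, col = linear_sum_assignment(cont, maximize=True)
    return float(cont[row, col].sum()) / truth.shape[0]


def nmi(truth, pred) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    truth, pred = _check_lengths(truth, pred)
    return float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))


def ari(truth, pred) -> float:
    """Adjusted Rand index over the pair-counting contingency table."""
    truth, pred = _check_lengths(truth, pred)
    return float(adjusted_rand_score(truth, pred))


def reference_annotate(
    query: np.ndarray,
    query_gene_ids: list[str],
    ref: ReferenceProfiles,
) -> tuple[list[str], np.ndarray]:
    """Assign each cell the reference type with the highest Pearson correlation.

    Correlations are computed on the shared gene set (matched by identifier);
    ties go to the first type in reference order, zero-variance profiles are
    skipped with a warning. Returns the assigned type names and the maximum
    correlation per cell.
    """
    query = np.atleast_2d(np.asarray(query, dtype=float))
    shared = [g for g in query_gene_ids if g in set(ref.gene_ids)]
    if len(shared) < 2:
        raise NoSharedGenesError(
            f"only {len(shared)} shared genes between query and reference"
        )
    q_idx = [query_gene_ids.index(g) for g in shared]
    r_idx = [ref.gene_ids.index(g) for g in shared]
    q = query[:, q_idx]
    r = ref.matrix[:, r_idx]

    r_sd = r.std(axis=1)
    usable = r_sd > 0
    for t, ok in zip(ref.type_names, usable):
        if not ok:
            logger.warning("reference profile %r has zero variance; skipped", t)
    if not usable.any():
        raise NoSharedGenesError("every reference profile is constant on the shared genes")

    qc = q - q.mean(axis=1, keepdims=True)
    rc = (r - r.mean(axis=1, keepdims=True))[usable]
    q_sd = qc.std(axis=1)
    denom = np.outer(q_sd, r_sd[usable]) * q.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qc @ rc.T) / np.maximum(denom, 1e-300)
    corr = np.where(q_sd[:, None] > 0, corr, -np.inf)

    usable_names = [t for t, ok in zip(ref.type_names, usable) if ok]
    best = np.argmax(corr, axis=1)  # first-wins on ties
    labels = [usable_names[b] for b in best]
    max_corr = corr[np.arange(q.shape[0]), best]
    return labels, max_corr
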
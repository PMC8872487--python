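"""Cell quality control, gene filtering and Pearson-residual normalization.

Cells with low total UMI or a high mitochondrial fraction are removed first,
then genes detected in too few cells, and finally the retained counts are
variance-stabilized with analytic Pearson residuals under a negative-binomial
null with fixed overdispersion, the standard normalization for UMI counts
ahead of network inference.  Order matters: dead genes are dropped before
they can influence the residual means.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataError, ParameterError, PipelineError
from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "default_mito_predicate",
    "qc_filter_cells",
    "filter_genes",
    "pearson_residuals",
    "PearsonResidualNormalizer",
]


@dataclass
class NormalizedMatrix:
    """Pearson-residual matrix (genes x cells) fed to network construction."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError("identifier lengths do not match matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise DataError("normalized matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def default_mito_predicate(gene_id: str) -> bool:
    """Mitochondrial gene rule: symbol starts with 'mt-' (case-insensitive)."""
    return gene_id.lower().startswith("mt-")


def qc_filter_cells(counts: CountMatrix,
                    mito_gene_predicate: Callable[[str], bool] | None = None,
                    min_umi: int = 1000,
                    max_mito_frac: float = 0.10) -> CountMatrix:
    """Drop low-quality cells.

    A cell is kept when its total UMI count is at least ``min_umi`` (cells
    with *fewer* counts are excluded) and its fraction of reads mapping to
    mitochondrial genes is at most ``max_mito_frac``.  Gene set and cell
    order are preserved.
    """
    if mito_gene_predicate is None:
        mito_gene_predicate = default_mito_predicate
    totals = counts.values.sum(axis=0)
    mito_rows = np.array([mito_gene_predicate(g) for g in counts.gene_ids],
                         dtype=bool)
    if mito_rows.any():
        mito_counts = counts.values[mito_rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    else:
        mito_frac = np.zeros_like(totals, dtype=float)
    umi_ok = totals >= min_umi
    mito_ok = mito_frac <= max_mito_frac
    keep = umi_ok & mito_ok
    if not keep.any():
        raise PipelineError(
            f"no cells survive QC: {int((~umi_ok).sum())} below {min_umi} UMIs, "
            f"{int((~mito_ok).sum())} above {max_mito_frac:.0%} mitochondrial reads")
    return CountMatrix(counts.values[:, keep], counts.gene_ids,
                       [c for c, k in zip(counts.cell_ids, keep) if k])


def filter_genes(counts: CountMatrix, min_cell_frac: float = 0.05) -> CountMatrix:
    """Keep genes with a nonzero count in at least ceil(frac * n) cells."""
    if not 0 < min_cell_frac < 1:
        raise ParameterError("min_cell_frac must lie strictly between 0 and 1")
    threshold = ceil(min_cell_frac * counts.n_cells)
    n_nonzero = (counts.values > 0).sum(axis=1)
    keep = n_nonzero >= threshold
    if not keep.any():
        raise PipelineError(
            f"no genes detected in >= {threshold} cells (frac {min_cell_frac})")
    return CountMatrix(counts.values[keep],
                       [g for g, k in zip(counts.gene_ids, keep) if k],
                       counts.cell_ids)


class PearsonResidualNormalizer(TransformerMixin, BaseEstimator):
    """Analytic Pearson residuals under an NB null with fixed overdispersion.

    For counts ``x`` (here samples = cells, features = genes, the sklearn
    orientation), the null mean is ``mu_cg = rowsum_c * colsum_g / total``
    and the residual ``(x - mu) / sqrt(mu + mu^2 / theta)``.  Entries with
    ``mu = 0`` are set to 0 (they carry no information).  With
    ``clip='sqrt-n'`` residuals are clamped to ``±sqrt(n_cells)``.

    Parameters
    ----------
    theta : float, default 100
        NB overdispersion of the null; ``theta -> inf`` recovers Poisson
        residuals.
    clip : {'sqrt-n', 'none'} or float, default 'sqrt-n'
        Symmetric clipping bound applied to the residuals.

    Attributes
    ----------
    clip_bound_ : float
        The bound actually applied by the last ``transform`` (inf for 'none').
    """

    def __init__(self, theta: float = 100.0, clip="sqrt-n"):
        self.theta = theta
        self.clip = clip

    def fit(self, X, y=None):
        if self.theta <= 0:
            raise ParameterError("theta must be positive")
        return self

    def transform(self, X):
        """Residuals of a cells x genes count array (same shape returned)."""
        self.fit(X)
        X = np.asarray(X, dtype=float)
        total = X.sum()
        if total <= 0:
            raise DataError("count matrix sums to zero")
        row = X.sum(axis=1, keepdims=True)   # per cell
        col = X.sum(axis=0, keepdims=True)   # per gene
        mu = row @ col / total
        denom = np.sqrt(mu + mu * mu / self.theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            resid = np.where(mu > 0, (X - mu) / np.where(denom > 0, denom, 1.0), 0.0)
        n_cells = X.shape[0]
        if self.clip == "sqrt-n":
            bound = float(np.sqrt(n_cells))
        elif self.clip == "none" or self.clip is None:
            bound = np.inf
        else:
            bound = float(self.clip)
            if bound <= 0:
                raise ParameterError("clip bound must be positive")
        self.clip_bound_ = bound
        if np.isfinite(bound):
            np.clip(resid, -bound, bound, out=resid)
        return resid


def pearson_residuals(counts: CountMatrix, theta: float = 100.0,
                      clip="sqrt-n") -> NormalizedMatrix:
    """Pearson-residual normalization of a genes x cells count matrix."""
    normalizer = PearsonResidualNormalizer(theta=theta, clip=clip)
    # transformer works in sklearn orientation (cells x genes)
    resid = normalizer.transform(counts.values.T).T
    return NormalizedMatrix(resid, list(counts.gene_ids), list(counts.cell_ids))
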
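"""Directed, weighted gene regulatory networks by principal-component
regression.

For each response gene, all other genes form the explanatory block
(cells x (p-1), column-centered).  The block's d leading principal
components are computed, the centered response is regressed on the
component scores by ordinary least squares, and the PC-space coefficients
are mapped back through the loadings onto the original genes.  Row i of the
resulting p x p adjacency matrix W holds the coefficients of every other
gene on response gene i (entry (i, j) = effect of regulator j on gene i);
the diagonal is zero.  With d = p-1 and a full-rank block this reduces
exactly to ordinary least squares; with d << n it is the usual low-rank
stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ParameterError
from .preprocess import NormalizedMatrix

__all__ = ["AdjacencyMatrix", "PCRegressionGRN", "pcr_single_gene",
           "build_grn", "normalize_grn"]


@dataclass
class AdjacencyMatrix:
    """GRN for one cell group: W[i, j] = coefficient of regulator j on gene i."""

    W: np.ndarray
    gene_ids: list[str]
    group_index: int = 0
    d_used: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        p = len(self.gene_ids)
        if self.W.shape != (p, p):
            raise ParameterError("W must be p x p with matching gene_ids")
        if not np.all(np.isfinite(self.W)):
            raise ParameterError("W contains non-finite entries")
        if np.any(np.diag(self.W) != 0):
            raise ParameterError("W diagonal must be exactly zero")


def _fix_component_signs(U: np.ndarray, Vt: np.ndarray) -> None:
    """Deterministic SVD orientation: largest-|loading| entry positive."""
    for comp in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0


class PCRegressionGRN(BaseEstimator):
    """Per-gene principal-component regression network estimator.

    Parameters
    ----------
    n_components : int, default 3
        Number of leading principal components (d).  Must satisfy
        ``1 <= d <= min(p - 1, n_cells - 1)``.
    scale_explanatory : bool, default False
        Scale explanatory columns to unit variance before PCA.  Off by
        default because Pearson residuals are already variance-stabilized.

    Attributes
    ----------
    adjacency_ : ndarray of shape (p, p)
        Row i = coefficients of all genes on response gene i; zero diagonal.
    n_features_in_ : int
    """

    def __init__(self, n_components: int = 3, scale_explanatory: bool = False):
        self.n_components = n_components
        self.scale_explanatory = scale_explanatory

    def fit(self, X, y=None):
        """Fit on a cells x genes matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2-dimensional (cells x genes)")
        n, p = X.shape
        d = self.n_components
        if n < 2:
            raise ParameterError("need at least two cells per group")
        if not 1 <= d <= min(p - 1, n - 1):
            raise ParameterError(
                f"n_components={d} outside [1, min(p-1, n-1)] = "
                f"[1, {min(p - 1, n - 1)}]")
        Xc = X - X.mean(axis=0, keepdims=True)
        if self.scale_explanatory:
            sd = Xc.std(axis=0, ddof=1)
            Xc = Xc / np.where(sd > 0, sd, 1.0)
        W = np.zeros((p, p))
        for j in range(p):
            W[j] = pcr_single_gene(Xc, j, d, _centered=True)
        self.adjacency_ = W
        self.n_features_in_ = p
        return self


def pcr_single_gene(X, response_index: int, d: int, *, _centered: bool = False) -> np.ndarray:
    """PC-regression coefficients of one response gene on all others.

    ``X`` is cells x genes.  Returns a length-p coefficient vector in the
    original gene order, with 0 at ``response_index``.  A zero-variance
    explanatory block yields all-zero coefficients.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= response_index < p:
        raise ParameterError("response_index out of range")
    if not 1 <= d <= min(p - 1, n - 1):
        raise ParameterError(
            f"d={d} outside [1, min(p-1, n-1)] = [1, {min(p - 1, n - 1)}]")
    if not _centered:
        X = X - X.mean(axis=0, keepdims=True)
    mask = np.arange(p) != response_index
    E = X[:, mask]
    y = X[:, response_index]
    U, S, Vt = np.linalg.svd(E, full_matrices=False)
    tol = max(E.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    if S.size == 0 or S[0] <= 0 or not np.isfinite(S[0]):
        return np.zeros(p)
    d_eff = min(d, int((S > tol).sum()))
    if d_eff == 0:
        return np.zeros(p)
    U, S, Vt = U[:, :d_eff].copy(), S[:d_eff], Vt[:d_eff].copy()
    _fix_component_signs(U, Vt)
    # scores = U * S are orthogonal, so OLS reduces to a diagonal solve
    gamma = (U.T @ y) / S
    coef = np.zeros(p)
    coef[mask] = Vt.T @ gamma
    return coef


def build_grn(X_group: NormalizedMatrix, d: int = 3, group_index: int = 0,
              scale_explanatory: bool = False) -> AdjacencyMatrix:
    """One GRN for a cell group (normalized genes x cells input)."""
    est = PCRegressionGRN(n_components=d, scale_explanatory=scale_explanatory)
    est.fit(X_group.values.T)
    return AdjacencyMatrix(est.adjacency_, list(X_group.gene_ids),
                           group_index=group_index, d_used=d)


def normalize_grn(adj: AdjacencyMatrix, method: str = "max-abs",
                  sparsify_top_frac: float = 1.0) -> AdjacencyMatrix:
    """Magnitude-normalize and optionally sparsify a network.

    ``max-abs`` divides all entries by the largest absolute entry so edge
    weights are comparable across groups; ``sparsify_top_frac < 1`` keeps
    only that fraction of off-diagonal entries with the largest magnitudes
    (ties broken by row-major position).
    """
    if method not in ("max-abs", "none"):
        raise ParameterError(f"unknown normalization method: {method!r}")
    if not 0 < sparsify_top_frac <= 1:
        raise ParameterError("sparsify_top_frac must lie in (0, 1]")
    W = adj.W.copy()
    if method == "max-abs":
        m = np.abs(W).max()
        if m > 0:
            W /= m
    if sparsify_top_frac < 1:
        p = W.shape[0]
        rows, cols = np.where(~np.eye(p, dtype=bool))
        vals = np.abs(W[rows, cols])
        m_keep = int(round(sparsify_top_frac * rows.size))
        # stable: descending magnitude, then (row, col)
        order = np.lexsort((cols, rows, -vals))
        drop = order[m_keep:]
        W[rows[drop], cols[drop]] = 0.0
    return AdjacencyMatrix(W, list(adj.gene_ids), group_index=adj.group_index,
                           d_used=adj.d_used)
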
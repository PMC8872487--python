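"""Gene embedding, clustering and Mahalanobis ranking of the slope matrix.

Each gene's profile in the slope matrix (its row = incoming regulation
trends, its column = outgoing, or both concatenated) is embedded into 2D
with t-SNE, the embedded genes are k-means clustered, and genes are ranked
by Mahalanobis distance to the embedding centroid.  Genes whose regulatory
interactions change strongly along pseudotime land in the periphery and top
the ranking; inert genes collapse to the center.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import DegenerateGeometryError, ParameterError
from .trend import SlopeMatrix

__all__ = ["gene_features", "embed_2d", "cluster_genes", "mahalanobis_rank",
           "GeneEmbedder"]


def gene_features(beta, mode: str = "concat") -> np.ndarray:
    """Per-gene feature vectors from the slope matrix.

    ``row``: gene as response (incoming regulation trends); ``col``: gene as
    regulator (outgoing); ``concat``: both, length 2p.
    """
    B = beta.beta if isinstance(beta, SlopeMatrix) else np.asarray(beta, dtype=float)
    if mode == "row":
        return B.copy()
    if mode == "col":
        return B.T.copy()
    if mode == "concat":
        return np.hstack([B, B.T])
    raise ParameterError(f"unknown feature mode: {mode!r}")


def embed_2d(features, seed: int, perplexity: float = 30.0,
             pca_predim: int = 50) -> np.ndarray:
    """Deterministic t-SNE of gene features into 2D.

    Features are optionally pre-reduced by PCA to
    ``min(pca_predim, n_features, p)`` dimensions first (the standard
    speed/noise trade-off for p x p inputs).
    """
    X = np.asarray(features, dtype=float)
    p, m = X.shape
    if p < 4:
        raise ParameterError("need at least 4 genes to embed")
    if perplexity >= p:
        raise ParameterError(f"perplexity {perplexity} too large for p={p}")
    if pca_predim and m > pca_predim:
        ndim = min(pca_predim, m, p)
        X = PCA(n_components=ndim, svd_solver="full",
                random_state=seed).fit_transform(X)
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed)
    return tsne.fit_transform(X)


def cluster_genes(coords, K: int = 50, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """K-means labels (1..K) on the 2D coords, relabeled by descending size."""
    coords = np.asarray(coords, dtype=float)
    p = coords.shape[0]
    if p < K:
        raise ParameterError(f"cannot form K={K} clusters from p={p} genes")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    raw = km.fit_predict(coords)
    sizes = np.bincount(raw, minlength=K)
    # largest cluster becomes label 1; ties keep the original label order
    order = np.lexsort((np.arange(K), -sizes))
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(1, K + 1)
    return relabel[raw]


def mahalanobis_rank(coords) -> tuple[np.ndarray, np.ndarray]:
    """Mahalanobis distance of every gene to the embedding centroid.

    Returns ``(mdist, rank_order)`` where ``rank_order`` sorts genes by
    descending distance (stable on ties).
    """
    coords = np.asarray(coords, dtype=float)
    p = coords.shape[0]
    if p < 3:
        raise ParameterError("need at least 3 genes for a sample covariance")
    mu = coords.mean(axis=0)
    cov = np.cov(coords, rowvar=False, ddof=1)
    if not np.all(np.isfinite(cov)) or abs(np.linalg.det(cov)) < 1e-300:
        raise DegenerateGeometryError("embedding covariance is singular")
    try:
        cho = linalg.cho_factor(cov)
    except linalg.LinAlgError as exc:
        raise DegenerateGeometryError("embedding covariance is singular") from exc
    diff = coords - mu
    mdist = np.sqrt(np.einsum("ij,ij->i", diff,
                              linalg.cho_solve(cho, diff.T).T))
    rank_order = np.argsort(-mdist, kind="stable")
    return mdist, rank_order


class GeneEmbedder(BaseEstimator):
    """End-to-end gene geometry: features -> t-SNE -> k-means -> ranking.

    Parameters
    ----------
    feature_mode : {'row', 'col', 'concat'}, default 'concat'
    perplexity : float, default 30
    pca_predim : int, default 50
    n_clusters : int, default 50
    n_init : int, default 10
    random_state : int, default 0
        Seeds both the embedding and the clustering.

    Attributes
    ----------
    coords_ : (p, 2) embedding coordinates
    labels_ : (p,) cluster labels in 1..K, numbered by descending size
    mdist_ : (p,) Mahalanobis distance to the embedding centroid
    rank_order_ : (p,) gene indices sorted by descending ``mdist_``
    """

    def __init__(self, feature_mode: str = "concat", perplexity: float = 30.0,
                 pca_predim: int = 50, n_clusters: int = 50, n_init: int = 10,
                 random_state: int = 0):
        self.feature_mode = feature_mode
        self.perplexity = perplexity
        self.pca_predim = pca_predim
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a p x p slope matrix (or a SlopeMatrix)."""
        feats = gene_features(X, self.feature_mode)
        self.coords_ = embed_2d(feats, seed=self.random_state,
                                perplexity=self.perplexity,
                                pca_predim=self.pca_predim)
        self.labels_ = cluster_genes(self.coords_, K=self.n_clusters,
                                     seed=self.random_state,
                                     n_init=self.n_init)
        self.mdist_, self.rank_order_ = mahalanobis_rank(self.coords_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
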
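"""Gene-set enrichment: local over-representation analysis and preranked GSEA.

Cluster enrichment uses the one-sided Fisher exact / hypergeometric
over-representation test against a user-supplied universe (all genes that
survived filtering).  The Mahalanobis-ranked gene list is scored with
preranked GSEA: a weighted Kolmogorov–Smirnov running sum whose hit
increments are proportional to |score|^weight, a gene-label permutation
null, sign-matched NES, and Benjamini–Hochberg FDR across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError
from .io import GeneSetCollection

__all__ = ["OraResult", "GseaResult", "ora_fisher", "ora_clusters",
           "gsea_preranked", "bh_fdr"]


@dataclass
class OraResult:
    set_name: str
    overlap_count: int
    set_size: int
    cluster_size: int
    universe_size: int
    p_value: float
    fdr_q: float = float("nan")
    overlap_genes: list[str] = field(default_factory=list)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float = float("nan")
    leading_edge: list[str] = field(default_factory=list)
    set_size: int = 0


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _norm(genes, case_insensitive: bool):
    return [g.upper() for g in genes] if case_insensitive else list(genes)


def ora_fisher(cluster_genes, gene_set, universe,
               case_insensitive: bool = False) -> OraResult:
    """One-sided hypergeometric over-representation test.

    ``p = P(overlap >= observed)`` when drawing ``|cluster|`` genes from the
    universe containing ``|set ∩ universe|`` set members.
    """
    uni = _norm(universe, case_insensitive)
    clu = _norm(cluster_genes, case_insensitive)
    gs = set(_norm(gene_set, case_insensitive))
    if not uni or not clu:
        raise ParameterError("universe and cluster must be non-empty")
    uni_set = set(uni)
    if not set(clu) <= uni_set:
        raise DataError("cluster genes must be a subset of the universe")
    set_in_uni = gs & uni_set
    overlap = [g for g in clu if g in set_in_uni]
    M, K, n, k = len(uni_set), len(set_in_uni), len(set(clu)), len(set(overlap))
    p = float(hypergeom.sf(k - 1, M, K, n))
    return OraResult(set_name="", overlap_count=k, set_size=K,
                     cluster_size=n, universe_size=M, p_value=min(p, 1.0),
                     overlap_genes=sorted(set(overlap)))


def ora_clusters(clusters: dict, collection: GeneSetCollection, universe,
                 case_insensitive: bool = False) -> dict:
    """ORA of every cluster against every set, BH-corrected within cluster."""
    out = {}
    for cname, genes in clusters.items():
        results = []
        for sname, members in collection.sets.items():
            r = ora_fisher(genes, members, universe,
                           case_insensitive=case_insensitive)
            r.set_name = sname
            results.append(r)
        if results:
            qs = bh_fdr([r.p_value for r in results])
            for r, q in zip(results, qs):
                r.fdr_q = float(q)
        out[cname] = results
    return out


def _running_extremum(run: np.ndarray) -> tuple[float, int]:
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def _es_stat(weights_full: np.ndarray, hit_mask: np.ndarray):
    """Running-sum ES for one set. ``weights_full`` = |score|^weight."""
    N = hit_mask.size
    h = int(hit_mask.sum())
    inc = np.full(N, -1.0 / (N - h))
    w = weights_full[hit_mask]
    s = w.sum()
    inc[hit_mask] = (w / s) if s > 0 else (1.0 / h)
    run = np.cumsum(inc)
    return _running_extremum(run)


def _perm_es(weights_full: np.ndarray, h: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_perm`` random size-h gene-label assignments (vectorized)."""
    N = weights_full.size
    miss = -1.0 / (N - h)
    idx = np.argpartition(rng.random((n_perm, N)), h - 1, axis=1)[:, :h]
    inc = np.full((n_perm, N), miss)
    w = weights_full[idx]
    s = w.sum(axis=1, keepdims=True)
    safe = np.where(s > 0, s, 1.0)
    vals = np.where(s > 0, w / safe, 1.0 / h)
    inc[np.arange(n_perm)[:, None], idx] = vals
    run = np.cumsum(inc, axis=1)
    pos = np.argmax(np.abs(run), axis=1)
    return run[np.arange(n_perm), pos]


def gsea_preranked(ranked_genes, scores, gene_sets: GeneSetCollection,
                   weight: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 5, max_size: int = 500,
                   case_insensitive: bool = False) -> list[GseaResult]:
    """Preranked GSEA of a descending-score gene list.

    Parameters
    ----------
    ranked_genes, scores
        Gene identifiers and their ranking scores, sorted descending
        (e.g. by Mahalanobis distance).
    weight
        Hit increments are proportional to ``|score|^weight`` (0 gives the
        classic unweighted Kolmogorov–Smirnov statistic).
    n_perm, seed
        Gene-label permutations for the null; fixed seed makes the p-values
        reproducible.
    min_size, max_size
        Sets with fewer/more members present in the ranked list are skipped.
    """
    names = _norm(ranked_genes, case_insensitive)
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(names):
        raise ParameterError("one score per ranked gene required")
    if scores.size and np.any(np.diff(scores) > 0):
        raise ParameterError("scores must be sorted descending")
    N = len(names)
    pos_of = {g: i for i, g in enumerate(names)}
    weights_full = np.abs(scores) ** weight if weight != 0 else np.ones(N)
    rng = np.random.default_rng(seed)
    results: list[GseaResult] = []
    for sname, members in gene_sets.sets.items():
        hit_idx = sorted({pos_of[m] for m in _norm(members, case_insensitive)
                          if m in pos_of})
        h = len(hit_idx)
        if h < min_size or h > max_size:
            continue
        if h == N:
            warnings.warn(f"gene set {sname!r} covers the whole ranked list; skipped")
            continue
        hit_mask = np.zeros(N, dtype=bool)
        hit_mask[hit_idx] = True
        es, ext = _es_stat(weights_full, hit_mask)
        perm = _perm_es(weights_full, h, n_perm, rng)
        if es >= 0:
            same = perm[perm >= 0]
            tail = int((same >= es).sum())
        else:
            same = perm[perm < 0]
            tail = int((same <= es).sum())
        p = (1 + tail) / (1 + same.size) if same.size else 1.0
        denom = float(np.abs(same).mean()) if same.size else 0.0
        nes = es / denom if denom > 0 else 0.0
        if es >= 0:
            lead = [names[i] for i in hit_idx if i <= ext]
        else:
            lead = [names[i] for i in hit_idx if i >= ext]
        results.append(GseaResult(set_name=sname, es=es, nes=nes,
                                  p_value=min(p, 1.0), leading_edge=lead,
                                  set_size=h))
    if results:
        qs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
    return results
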
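"""End-to-end orchestration: config, validation, staged execution, manifest.

The pipeline runs preprocess -> binning -> per-group GRN -> trend regression
-> gene embedding -> enrichment (+ optional regulator report), writing each
stage's artifact to the output directory and recording a manifest with a
config hash and per-stage SHA-256 checksums.  Identical config and seeds
give identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binning import make_partition
from .embedding import GeneEmbedder
from .enrichment import gsea_preranked, ora_clusters
from .errors import DataError, ParameterError
from .grn import build_grn, normalize_grn
from .io import (read_counts, read_gmt, read_pseudotime, write_matrix)
from .preprocess import filter_genes, pearson_residuals, qc_filter_cells
from .regulators import regulator_report
from .trend import edge_slopes
from .preprocess import NormalizedMatrix

__all__ = ["PipelineConfig", "Finding", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (file keys use dots, e.g. ``qc.min_umi``)."""

    counts: str = ""
    counts_dialect: str = "mtx-triplet"
    genes_as_rows: bool = True
    pseudotime: str = ""
    gmt: str | None = None
    out_dir: str = "grntrend_out"
    qc_min_umi: int = 1000
    qc_max_mito_frac: float = 0.10
    qc_mito_prefixes: tuple = ("mt-",)
    genes_min_cell_frac: float = 0.05
    norm_theta: float = 100.0
    norm_clip: str = "sqrt-n"
    groups_k: int = 10
    groups_min_size: int = 500
    grn_d: int = 3
    grn_scale_explanatory: bool = False
    grn_normalize: str = "max-abs"
    grn_sparsify_top_frac: float = 1.0
    feature_mode: str = "concat"
    embed_seed: int = 0
    embed_perplexity: float = 30.0
    embed_pca_predim: int = 50
    cluster_k: int = 50
    cluster_seed: int = 0
    cluster_n_init: int = 10
    mdist_robust: bool = False
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    gsea_seed: int = 0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    sets_case_insensitive: bool = False
    regulator_target: str | None = None
    regulator_top: int = 30

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParameterError("config file must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            attr = str(key).replace(".", "_").replace("-", "_")
            if attr not in known:
                raise ParameterError(f"unknown config key: {key!r}")
            kwargs[attr] = value
        cfg = cls(**kwargs)
        if isinstance(cfg.qc_mito_prefixes, str):
            cfg.qc_mito_prefixes = tuple(
                s.strip() for s in cfg.qc_mito_prefixes.split(",") if s.strip())
        else:
            cfg.qc_mito_prefixes = tuple(cfg.qc_mito_prefixes)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class Finding:
    level: str   # "error" | "warning"
    code: str
    message: str


def _count_data_rows(path: Path) -> int | None:
    try:
        with open(path) as fh:
            rows = sum(1 for line in fh if line.strip())
        return max(rows - 1, 0)  # allow for a header row
    except OSError:
        return None


def validate_config(cfg: PipelineConfig) -> list[Finding]:
    """Static checks; returns findings instead of raising."""
    findings: list[Finding] = []
    if not cfg.counts or not Path(cfg.counts).exists():
        findings.append(Finding("error", "missing-counts",
                                f"counts path does not exist: {cfg.counts!r}"))
    if not cfg.pseudotime or not Path(cfg.pseudotime).exists():
        findings.append(Finding("error", "missing-pseudotime",
                                f"pseudotime path does not exist: {cfg.pseudotime!r}"))
    if cfg.gmt and not Path(cfg.gmt).exists():
        findings.append(Finding("error", "missing-gmt",
                                f"GMT path does not exist: {cfg.gmt!r}"))
    if cfg.groups_k < 3:
        findings.append(Finding("error", "k-too-small",
                                "groups.k must be >= 3 for a slope with residual df"))
    if not 0 < cfg.genes_min_cell_frac < 1:
        findings.append(Finding("error", "bad-gene-frac",
                                "genes.min_cell_frac must lie in (0, 1)"))
    if cfg.norm_theta <= 0:
        findings.append(Finding("error", "bad-theta", "norm.theta must be > 0"))
    if cfg.grn_d < 1:
        findings.append(Finding("error", "bad-d", "grn.d must be >= 1"))
    if cfg.pseudotime and Path(cfg.pseudotime).exists():
        n = _count_data_rows(Path(cfg.pseudotime))
        if n and cfg.groups_k >= 2:
            w = min(n, cfg.groups_min_size)
            if n // cfg.groups_k < cfg.groups_min_size:
                step = (n - w) / (cfg.groups_k - 1)
                shared = 1.0 - step / w if w else 1.0
                if shared > 0.8:
                    findings.append(Finding(
                        "warning", "heavy-overlap",
                        f"consecutive groups share {shared:.0%} of their cells "
                        f"(n={n}, k={cfg.groups_k}, min_size={cfg.groups_min_size})"))
            if n < min(cfg.groups_k, cfg.groups_min_size):
                findings.append(Finding("error", "too-few-cells",
                                        f"only {n} cells for the requested grouping"))
    return findings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _mito_predicate(prefixes: tuple):
    lowered = tuple(p.lower() for p in prefixes)
    return lambda g: g.lower().startswith(lowered)


def run_pipeline(cfg: PipelineConfig, log=None) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    errors = validate_config(cfg)
    hard = [f for f in errors if f.level == "error"]
    if hard:
        raise ParameterError("; ".join(f"{f.code}: {f.message}" for f in hard))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: dict[str, dict] = {}

    def emit(name: str, path: Path, shape) -> None:
        stages[name] = {"path": str(path.relative_to(out)),
                        "sha256": _sha256(path), "shape": list(shape)}
        if log:
            log(f"[{name}] {path.name} shape={tuple(shape)}")

    counts = read_counts(cfg.counts, dialect=cfg.counts_dialect,
                         genes_as_rows=cfg.genes_as_rows)
    pt_all = read_pseudotime(cfg.pseudotime)
    common = [c for c in counts.cell_ids if c in set(pt_all.cell_ids)]
    if len(common) < 2:
        raise DataError("counts and pseudotime share fewer than two cells")
    if len(common) < counts.n_cells:
        keep = {c: i for i, c in enumerate(counts.cell_ids)}
        idx = [keep[c] for c in common]
        from .io import CountMatrix
        counts = CountMatrix(counts.values[:, idx], counts.gene_ids, common)

    counts = qc_filter_cells(counts, _mito_predicate(cfg.qc_mito_prefixes),
                             min_umi=cfg.qc_min_umi,
                             max_mito_frac=cfg.qc_max_mito_frac)
    counts = filter_genes(counts, min_cell_frac=cfg.genes_min_cell_frac)
    norm = pearson_residuals(counts, theta=cfg.norm_theta, clip=cfg.norm_clip)
    norm_path = out / "normalized.csv"
    pd.DataFrame(norm.values, index=norm.gene_ids,
                 columns=norm.cell_ids).to_csv(norm_path, float_format="%.10g")
    emit("normalized", norm_path, norm.values.shape)

    pt = pt_all.subset(norm.cell_ids)
    partition = make_partition(pt, k=cfg.groups_k, min_size=cfg.groups_min_size)
    part_rows = []
    for i, (s, e) in enumerate(partition.windows):
        cells = partition.group_cell_indices(i)
        part_rows.append({"group": i + 1, "start": s, "end": e, "size": e - s,
                          "mean_time": float(pt.times[cells].mean()),
                          "t": float(partition.t[i])})
    part_path = out / "partition.csv"
    pd.DataFrame(part_rows).to_csv(part_path, index=False, float_format="%.10g")
    emit("partition", part_path, (partition.k, 6))

    W_list = []
    for i in range(partition.k):
        cells = partition.group_cell_indices(i)
        sub = NormalizedMatrix(norm.values[:, cells], norm.gene_ids,
                               [norm.cell_ids[c] for c in cells])
        adj = build_grn(sub, d=cfg.grn_d, group_index=i,
                        scale_explanatory=cfg.grn_scale_explanatory)
        adj = normalize_grn(adj, method=cfg.grn_normalize,
                            sparsify_top_frac=cfg.grn_sparsify_top_frac)
        w_path = out / f"W_{i + 1:02d}.csv"
        write_matrix(adj.W, adj.gene_ids, w_path, fmt="dense-csv")
        emit(f"grn_{i + 1:02d}", w_path, adj.W.shape)
        W_list.append(adj)

    slopes = edge_slopes(W_list, partition.t)
    beta_path = out / "beta.csv"
    write_matrix(slopes.beta, slopes.gene_ids, beta_path, fmt="dense-csv")
    emit("beta", beta_path, slopes.beta.shape)

    p = len(slopes.gene_ids)
    perplexity = cfg.embed_perplexity
    n_clusters = min(cfg.cluster_k, p)
    embedder = GeneEmbedder(feature_mode=cfg.feature_mode,
                            perplexity=perplexity,
                            pca_predim=cfg.embed_pca_predim,
                            n_clusters=n_clusters,
                            n_init=cfg.cluster_n_init,
                            random_state=cfg.embed_seed).fit(slopes)
    rank = np.empty(p, dtype=int)
    rank[embedder.rank_order_] = np.arange(1, p + 1)
    genes_df = pd.DataFrame({
        "gene": slopes.gene_ids,
        "x": embedder.coords_[:, 0], "y": embedder.coords_[:, 1],
        "cluster": embedder.labels_, "mdist": embedder.mdist_, "rank": rank,
    })
    genes_path = out / "genes.csv"
    genes_df.to_csv(genes_path, index=False, float_format="%.10g")
    emit("embedding", genes_path, genes_df.shape)

    if cfg.gmt:
        collection = read_gmt(cfg.gmt)
        universe = list(slopes.gene_ids)
        clusters = {int(c): genes_df.loc[genes_df["cluster"] == c, "gene"].tolist()
                    for c in sorted(genes_df["cluster"].unique())}
        ora = ora_clusters(clusters, collection, universe,
                           case_insensitive=cfg.sets_case_insensitive)
        ora_rows = [{"cluster": c, "set": r.set_name, "overlap": r.overlap_count,
                     "set_size": r.set_size, "cluster_size": r.cluster_size,
                     "p_value": r.p_value, "fdr_q": r.fdr_q,
                     "overlap_genes": ";".join(r.overlap_genes)}
                    for c, rs in ora.items() for r in rs]
        ora_path = out / "ora.csv"
        pd.DataFrame(ora_rows).to_csv(ora_path, index=False, float_format="%.10g")
        emit("ora", ora_path, (len(ora_rows), 8))

        order = embedder.rank_order_
        ranked = [slopes.gene_ids[i] for i in order]
        scores = embedder.mdist_[order]
        gsea = gsea_preranked(ranked, scores, collection,
                              weight=cfg.gsea_weight, n_perm=cfg.gsea_n_perm,
                              seed=cfg.gsea_seed, min_size=cfg.gsea_min_size,
                              max_size=cfg.gsea_max_size,
                              case_insensitive=cfg.sets_case_insensitive)
        gsea_rows = [{"set": r.set_name, "size": r.set_size, "es": r.es,
                      "nes": r.nes, "p_value": r.p_value, "fdr_q": r.fdr_q,
                      "leading_edge": ";".join(r.leading_edge)} for r in gsea]
        gsea_path = out / "gsea.csv"
        pd.DataFrame(gsea_rows).to_csv(gsea_path, index=False, float_format="%.10g")
        emit("gsea", gsea_path, (len(gsea_rows), 7))

    if cfg.regulator_target:
        report = regulator_report(slopes, W_list, cfg.regulator_target,
                                  N=cfg.regulator_top)
        reg_path = out / "regulators.csv"
        pd.DataFrame({"regulator": [g for g, _ in report.regulators],
                      "beta": [b for _, b in report.regulators],
                      "sign": report.signs}).to_csv(
            reg_path, index=False, float_format="%.10g")
        emit("regulators", reg_path, (len(report.regulators), 3))
        traj_path = out / "trajectories.csv"
        pd.DataFrame(report.trajectories,
                     columns=[g for g, _ in report.regulators]).to_csv(
            traj_path, index=False, float_format="%.10g")
        emit("trajectories", traj_path, report.trajectories.shape)

    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "stages": stages,
        "wall_time_s": round(time.time() - t0, 3),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
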
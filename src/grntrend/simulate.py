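"""Synthetic UMI counts with a known latent time and known time-varying
regulatory edges.

Each cell carries a latent time s ~ Uniform(0,1).  Regulator genes follow
smooth sine/linear expression programs of s; each planted edge
(response, regulator, a, b) makes the response's latent expression include
the term ``(a + b*s) * r(s)``, so the regulation strength changes linearly
in time with slope sign sign(b) — exactly the trend the pipeline estimates.
Remaining genes are independent noise ("null") genes.  Latents are shifted
to positive means, scaled to per-cell relative abundances, multiplied by a
log-normal sequencing depth, and sampled as Poisson (or gamma-Poisson
negative binomial) counts.

The defaults define the reference recovery experiment: 50 genes, 2000
cells, 10 planted edges of slope magnitude 1, latent noise SD 0.1, Poisson
counts at 2000 expected UMIs per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io import (CountMatrix, GeneSetCollection, PseudotimeAssignment,
                 write_counts, write_gmt, write_pseudotime)

__all__ = ["SimulationSpec", "SimulationTruth", "default_edges", "simulate",
           "make_fixture_suite"]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic data set."""

    p: int = 50
    n: int = 2000
    n_regulators: int = 5
    n_edges: int = 10
    edges: list[tuple[int, int, float, float]] | None = None
    noise_sd: float = 0.1
    count_model: str = "poisson"      # or "negative-binomial"
    theta: float = 100.0              # NB overdispersion if used
    depth_mean: float = 2000.0
    depth_sigma: float = 0.3          # log-normal depth spread
    weight_shape: str = "linear"      # or "logistic" (switch-like trend,
                                      # for robustness experiments only)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edges is None:
            self.edges = default_edges(self.p, self.n_regulators, self.n_edges)
        for resp, reg, _a, _b in self.edges:
            if resp == reg:
                raise ParameterError("an edge cannot be a self-loop")
            if not (0 <= reg < self.p and 0 <= resp < self.p):
                raise ParameterError("edge indices out of range")
        n_resp = len({e[0] for e in self.edges})
        if self.p < self.n_regulators + n_resp:
            raise ParameterError("p too small for regulators plus responses")
        if self.depth_mean <= 0:
            raise ParameterError("depth_mean must be positive")
        if self.count_model not in ("poisson", "negative-binomial"):
            raise ParameterError(f"unknown count model: {self.count_model!r}")
        if self.weight_shape not in ("linear", "logistic"):
            raise ParameterError(f"unknown weight shape: {self.weight_shape!r}")


@dataclass
class SimulationTruth:
    counts: CountMatrix
    true_time: np.ndarray
    true_edges: list[tuple[int, int, float, float]]
    gene_roles: dict[str, str] = field(default_factory=dict)


def default_edges(p: int, n_regulators: int,
                  n_edges: int | None = None) -> list[tuple[int, int, float, float]]:
    """Planted edges: regulators drive distinct response genes round-robin,
    so each master regulator controls several targets.

    Slopes alternate between +1 and -1; baselines keep the weight
    ``a + b*s`` inside [0.5, 1.5] over s in [0, 1].
    """
    if n_edges is None:
        n_edges = 2 * n_regulators
    if p < n_regulators + n_edges:
        raise ParameterError("p too small for the requested edge count")
    edges = []
    for j in range(n_edges):
        b = 1.0 if j % 2 == 0 else -1.0
        a = 0.5 if b > 0 else 1.5
        edges.append((n_regulators + j, j % n_regulators, a, b))
    return edges


def _gene_ids(spec: SimulationSpec) -> tuple[list[str], dict[str, str]]:
    responses = sorted({e[0] for e in spec.edges})
    regulators = sorted({e[1] for e in spec.edges})
    ids, roles = [], {}
    for g in range(spec.p):
        if g in regulators:
            name = f"reg{g:03d}"
            roles[name] = "regulator"
        elif g in responses:
            name = f"tgt{g:03d}"
            roles[name] = "response"
        else:
            name = f"null{g:03d}"
            roles[name] = "null"
        ids.append(name)
    return ids, roles


def simulate(spec: SimulationSpec) -> SimulationTruth:
    """Draw one synthetic data set; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    p, n = spec.p, spec.n
    s = rng.uniform(0.0, 1.0, size=n)

    latent = np.empty((p, n))
    regulators = sorted({e[1] for e in spec.edges})
    responses = {e[0] for e in spec.edges}
    # Regulator programs are sine/linear mixtures over a shared
    # low-dimensional smooth basis — a linear ramp plus a quadrature sine
    # pair at two cycles per unit time — mirroring the low-rank expression
    # manifolds PC regression assumes.  The quadrature pair keeps every
    # program's local variance high at all times (a single sine is flat
    # near its extrema, which would leave the regulator unmeasurable in
    # some pseudotime windows); each regulator draws its own unit-norm
    # mixture, so programs are related but not collinear, and adds
    # independent noise.
    phase = rng.uniform(0.0, 2 * np.pi)
    basis = np.stack([s - 0.5,
                      np.sin(4 * np.pi * s + phase),
                      np.cos(4 * np.pi * s + phase)])
    mix = rng.uniform(-0.5, 0.5, size=(len(regulators), 3))
    mix /= np.maximum(np.linalg.norm(mix, axis=1, keepdims=True), 1e-12)
    reg_expr = {}
    for m, g in enumerate(regulators):
        base = 1.0 + mix[m] @ basis
        reg_expr[g] = base
        latent[g] = base + rng.normal(0.0, spec.noise_sd, size=n)
    for g in responses:
        latent[g] = rng.normal(0.0, spec.noise_sd, size=n)
    if spec.weight_shape == "logistic":
        # switch-like trend with the same endpoints as the linear ramp
        s_eff = 1.0 / (1.0 + np.exp(-(s - 0.5) / 0.1))
    else:
        s_eff = s
    for resp, reg, a, b in spec.edges:
        latent[resp] = latent[resp] + (a + b * s_eff) * reg_expr[reg]
    for g in range(p):
        if g not in reg_expr and g not in responses:
            latent[g] = 1.0 + rng.normal(0.0, spec.noise_sd, size=n)

    # shift every gene to a strictly positive abundance scale
    lo = latent.min(axis=1, keepdims=True)
    shift = np.where(lo < 0.1, 0.1 - lo, 0.0)
    abundance = latent + shift
    if abundance.min() <= 0:  # recompute with a safety margin
        abundance = latent - latent.min() + 0.1
    fractions = abundance / abundance.sum(axis=0, keepdims=True)

    mu_log = np.log(spec.depth_mean) - spec.depth_sigma ** 2 / 2.0
    depth = rng.lognormal(mean=mu_log, sigma=spec.depth_sigma, size=n)
    mean = fractions * depth[np.newaxis, :]
    if spec.count_model == "negative-binomial":
        mean = rng.gamma(shape=spec.theta, scale=mean / spec.theta)
    counts = rng.poisson(mean)

    gene_ids, roles = _gene_ids(spec)
    cell_ids = [f"cell{c:05d}" for c in range(n)]
    return SimulationTruth(
        counts=CountMatrix(counts, gene_ids, cell_ids),
        true_time=s,
        true_edges=list(spec.edges),
        gene_roles=roles,
    )


def truth_gene_sets(truth: SimulationTruth) -> GeneSetCollection:
    """Three gene sets: planted-edge genes, null genes, and a mixed decoy."""
    planted = [g for g, r in truth.gene_roles.items() if r != "null"]
    nulls = [g for g, r in truth.gene_roles.items() if r == "null"]
    half = max(1, len(planted) // 2)
    decoy = planted[:half] + nulls[: max(1, len(nulls) // 2)]
    return GeneSetCollection(
        sets={"planted": planted, "background": nulls, "decoy": decoy},
        descriptions={"planted": "genes on planted time-varying edges",
                      "background": "independent noise genes",
                      "decoy": "half planted, half background"})


def make_fixture_suite(out_dir: str | Path, seed: int = 0,
                       n_fixtures: int = 5) -> list[Path]:
    """Write small canonical fixture triplets (counts, pseudotime, GMT).

    Each fixture directory holds an MTX-triplet count matrix with sidecars,
    a dense CSV copy, the true latent time as the pseudotime table, and a
    GMT with a "planted" set.  Regeneration with the same seed is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dirs = []
    for i in range(n_fixtures):
        spec = SimulationSpec(p=20, n=300, n_regulators=4,
                              edges=default_edges(20, 4),
                              depth_mean=500.0, seed=seed + i)
        truth = simulate(spec)
        d = out_dir / f"fixture{i:02d}"
        d.mkdir(parents=True, exist_ok=True)
        write_counts(truth.counts, d / "matrix.mtx", dialect="mtx-triplet")
        write_counts(truth.counts, d / "counts.csv", dialect="dense-csv")
        write_pseudotime(
            PseudotimeAssignment(truth.counts.cell_ids, truth.true_time),
            d / "pseudotime.csv")
        write_gmt(truth_gene_sets(truth), d / "sets.gmt")
        dirs.append(d)
    return dirs
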
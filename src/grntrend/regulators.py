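"""Regulator reports: top-N regulators of a target gene, their per-group edge
trajectories (heatmap input), and a signed regulation model.

"Regulators of g" reads row g of the slope matrix — the incoming edges onto
g as response, following the adjacency orientation where entry (i, j) is the
coefficient of regulator j on response gene i.  A positive slope means the
regulation strengthens along pseudotime; a negative one, that it weakens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeneLookupError, ParameterError
from .grn import AdjacencyMatrix
from .trend import SlopeMatrix

__all__ = ["RegulatorReport", "top_regulators", "edge_trajectories",
           "sign_model", "regulator_report"]


@dataclass
class RegulatorReport:
    target: str
    regulators: list[tuple[str, float]]      # (gene, beta), descending |beta|
    trajectories: np.ndarray                 # k x N edge weights
    signs: list[int]                         # sign(beta) per regulator
    t: np.ndarray | None = None


def top_regulators(beta: SlopeMatrix, target: str, N: int = 30,
                   use_column: bool = False) -> list[tuple[str, float]]:
    """The N regulators of ``target`` with the largest |slope|.

    Ties are broken by gene order.  ``use_column=True`` flips the convention
    and reads the target's column (outgoing edges) instead.
    """
    ti = beta.gene_index(target)
    row = beta.beta[:, ti] if use_column else beta.beta[ti]
    idx = np.arange(len(beta.gene_ids))
    mask = idx != ti
    cand = idx[mask]
    order = np.lexsort((cand, -np.abs(row[cand])))
    chosen = cand[order][:N]
    return [(beta.gene_ids[j], float(row[j])) for j in chosen]


def edge_trajectories(W_list: list[AdjacencyMatrix], target: str,
                      regulators: list[str]) -> np.ndarray:
    """k x N matrix of edge weights W_m[target, regulator] per group m."""
    if not W_list:
        raise ParameterError("need at least one group network")
    gene_ids = list(W_list[0].gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    try:
        ti = index[target]
        ridx = [index[r] for r in regulators]
    except KeyError as exc:
        raise GeneLookupError(str(exc.args[0])) from None
    return np.stack([adj.W[ti, ridx] for adj in W_list])


def sign_model(beta: SlopeMatrix, genes: list[str],
               threshold: float = 0.0) -> list[tuple[str, str, int]]:
    """Signed edges among ``genes``: (response, regulator, sign of slope).

    Edges with ``|beta| >= threshold`` are emitted; the default threshold 0
    keeps every ordered pair.  Sign +1 marks regulation that strengthens
    along pseudotime, -1 regulation that weakens.
    """
    if len(genes) < 2:
        raise ParameterError("need at least two genes for a regulation model")
    idx = [beta.gene_index(g) for g in genes]
    edges = []
    for gi, i in zip(genes, idx):
        for gj, j in zip(genes, idx):
            if i == j:
                continue
            b = beta.beta[i, j]
            if abs(b) >= threshold:
                edges.append((gi, gj, int(np.sign(b))))
    return edges


def regulator_report(beta: SlopeMatrix, W_list: list[AdjacencyMatrix],
                     target: str, N: int = 30,
                     use_column: bool = False) -> RegulatorReport:
    """Bundle top regulators, their trajectories, and slope signs."""
    regs = top_regulators(beta, target, N=N, use_column=use_column)
    names = [g for g, _ in regs]
    traj = edge_trajectories(W_list, target, names)
    return RegulatorReport(target=target, regulators=regs, trajectories=traj,
                           signs=[int(np.sign(b)) for _, b in regs],
                           t=np.asarray(beta.t_used, dtype=float))
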
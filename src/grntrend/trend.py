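"""Per-edge trend regression: the slope matrix.

Each edge weight is tracked across the k group networks and regressed on the
normalized group time by simple least squares.  The slope
``beta_ij = sum_m (t_m - tbar)(W_ij^m - Wbar_ij) / sum_m (t_m - tbar)^2``
is positive when the regulation of gene i by gene j strengthens along
pseudotime and negative when it weakens.  The p x p matrix of slopes is the
object every downstream ranking step consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DegenerateTimeError, ParameterError
from .grn import AdjacencyMatrix

__all__ = ["SlopeMatrix", "edge_slopes"]


@dataclass
class SlopeMatrix:
    """Slopes of edge weight on group time; diagonal zero like every W."""

    beta: np.ndarray
    gene_ids: list[str]
    t_used: np.ndarray
    intercept: np.ndarray | None = None
    r2: np.ndarray | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        p = len(self.gene_ids)
        if self.beta.shape != (p, p):
            raise ParameterError("beta must be p x p with matching gene_ids")
        if not np.all(np.isfinite(self.beta)):
            raise ParameterError("beta contains non-finite entries")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene_index(self, gene: str) -> int:
        from .errors import GeneLookupError
        try:
            return self._index[gene]
        except KeyError:
            raise GeneLookupError(gene) from None


def edge_slopes(W_list: list[AdjacencyMatrix], t, diagnostics: bool = True) -> SlopeMatrix:
    """Regress every edge weight on normalized group time.

    Parameters
    ----------
    W_list
        k >= 3 group networks sharing gene identifiers and order.
    t
        Strictly increasing group times (length k).
    diagnostics
        Also compute per-edge intercepts and R^2 (not used downstream).
    """
    t = np.asarray(t, dtype=float)
    k = len(W_list)
    if k < 3:
        raise ParameterError("need at least 3 group networks for a trend")
    if t.size != k:
        raise ParameterError("one time value per network required")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("group times must be strictly increasing")
    gene_ids = list(W_list[0].gene_ids)
    for adj in W_list[1:]:
        if list(adj.gene_ids) != gene_ids:
            raise DataError("group networks disagree on gene identifiers")
    stack = np.stack([adj.W for adj in W_list])  # k x p x p
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0:
        raise DegenerateTimeError("group times carry no variance")
    Wbar = stack.mean(axis=0)
    beta = np.tensordot(tc, stack - Wbar, axes=(0, 0)) / denom
    intercept = r2 = None
    if diagnostics:
        intercept = Wbar - beta * t.mean()
        total = ((stack - Wbar) ** 2).sum(axis=0)
        explained = (beta ** 2) * denom
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(total > 0, explained / np.where(total > 0, total, 1.0), 0.0)
    return SlopeMatrix(beta, gene_ids, t.copy(), intercept=intercept, r2=r2)
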
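"""Pseudotime binning: order cells, split them into k ordered (possibly
overlapping) groups with a minimum-size guarantee, and compute each group's
normalized mean pseudotime.

When ``floor(n/k) >= min_size`` the groups are disjoint consecutive windows
of equal width (remainder appended to the last); otherwise k fixed-width
windows of ``min(n, min_size)`` cells are placed with evenly spaced starts,
so the first begins at the first cell and the last ends at the last cell.
Group mean pseudotimes are min-max normalized onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTimeError, ParameterError
from .io import PseudotimeAssignment

__all__ = ["GroupPartition", "order_cells", "split_groups", "group_times",
           "make_partition"]


@dataclass
class GroupPartition:
    """k ordered windows into the pseudotime-sorted cell order.

    ``windows`` are 0-based half-open ``(start, end)`` pairs indexing into
    ``sort_order`` (a permutation of original cell indices); ``t`` holds the
    normalized group mean pseudotimes.
    """

    windows: list[tuple[int, int]]
    t: np.ndarray
    sort_order: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sort_order = np.asarray(self.sort_order, dtype=int)
        if len(self.windows) != self.t.size:
            raise ParameterError("one normalized time per window required")

    @property
    def k(self) -> int:
        return len(self.windows)

    def group_cell_indices(self, i: int) -> np.ndarray:
        """Original cell indices of group i."""
        s, e = self.windows[i]
        return self.sort_order[s:e]


def order_cells(pt: PseudotimeAssignment) -> np.ndarray:
    """Stable ascending sort of cells by pseudotime (ties keep input order)."""
    if pt.times.size < 2:
        raise ParameterError("need at least two cells to order")
    return np.argsort(pt.times, kind="stable")


def split_groups(n: int, k: int = 10, min_size: int = 500) -> list[tuple[int, int]]:
    """Window boundaries for k ordered groups over n sorted cells."""
    if k < 2:
        raise ParameterError("need at least k=2 groups")
    if n < min(k, min_size):
        raise ParameterError(
            f"too few cells (n={n}) for k={k} groups of min_size={min_size}")
    base = n // k
    if base >= min_size:
        windows = [(i * base, (i + 1) * base) for i in range(k)]
        windows[-1] = (windows[-1][0], n)  # remainder joins the last window
        return windows
    w = min(n, min_size)
    starts = [round((i * (n - w)) / (k - 1)) for i in range(k)]
    return [(s, s + w) for s in starts]


def group_times(pt: PseudotimeAssignment, partition: GroupPartition) -> np.ndarray:
    """Min-max normalized mean pseudotime per group (t_1 = 0, t_k = 1)."""
    means = np.array([pt.times[partition.group_cell_indices(i)].mean()
                      for i in range(partition.k)])
    lo, hi = means.min(), means.max()
    if hi == lo:
        raise DegenerateTimeError(
            "all group mean pseudotimes are equal; trend slopes undefined")
    return (means - lo) / (hi - lo)


def make_partition(pt: PseudotimeAssignment, k: int = 10,
                   min_size: int = 500) -> GroupPartition:
    """Order cells, window them, and attach normalized group times."""
    order = order_cells(pt)
    windows = split_groups(pt.times.size, k=k, min_size=min_size)
    partition = GroupPartition(windows, np.zeros(len(windows)), order)
    t = group_times(pt, partition)
    if np.any(np.diff(t) <= 0):
        raise DegenerateTimeError(
            "group mean pseudotimes are not strictly increasing; "
            "reduce k or min_size (heavily overlapping windows)")
    partition.t = t
    return partition
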
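"""Readers and writers for the on-disk formats the pipeline touches.

Everything downstream of this module works on in-memory domain containers:
:class:`CountMatrix` (raw UMI counts, genes x cells),
:class:`PseudotimeAssignment` (per-cell pseudotime) and
:class:`GeneSetCollection` (GMT gene sets).  Supported formats are
MatrixMarket triplets with 10x-style ``features.tsv``/``barcodes.tsv``
sidecars (gzipped variants accepted), dense CSV/TSV with gene and cell
identifiers, two-column pseudotime tables, and GMT.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "CountMatrix",
    "PseudotimeAssignment",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_pseudotime",
    "write_pseudotime",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise DataError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class CountMatrix:
    """Raw UMI counts for p genes (rows) in n cells (columns)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataError("count matrix must be two-dimensional")
        p, n = self.values.shape
        if len(self.gene_ids) != p or len(self.cell_ids) != n:
            raise DataError(
                f"identifier lengths ({len(self.gene_ids)}, {len(self.cell_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            flo = np.asarray(self.values, dtype=float)
            if not np.all(np.isfinite(flo)):
                raise DataError("counts contain non-finite entries")
            if np.any(flo != np.round(flo)):
                raise DataError("counts contain fractional entries")
            self.values = flo.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise DataError("counts contain negative entries")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class PseudotimeAssignment:
    """Per-cell nonnegative pseudotime, in arbitrary units."""

    cell_ids: list[str]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.cell_ids) != self.times.size:
            raise DataError("pseudotime needs exactly one value per cell")
        if not np.all(np.isfinite(self.times)):
            raise DataError("pseudotime contains non-finite values")
        if self.times.size and self.times.min() < 0:
            raise DataError("pseudotime contains negative values")
        _check_unique(self.cell_ids, "cell")

    def subset(self, cell_ids: list[str]) -> "PseudotimeAssignment":
        """Restrict to ``cell_ids``, in the given order."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in index]
        if missing:
            raise DataError(f"cells without pseudotime: {missing[:5]} ...")
        idx = [index[c] for c in cell_ids]
        return PseudotimeAssignment(list(cell_ids), self.times[idx])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty members."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_sidecar(mtx_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in (".tsv", ".tsv.gz", ".txt", ".txt.gz"):
            cand = mtx_path.parent / f"{stem}{suffix}"
            if cand.exists():
                return cand
    raise FormatError(
        f"missing sidecar ({' or '.join(stems)}) next to {mtx_path}"
    )


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts(path: str | Path, dialect: str = "mtx-triplet",
                genes_as_rows: bool = True) -> CountMatrix:
    """Read a raw count matrix.

    Parameters
    ----------
    path
        For ``mtx-triplet``, the ``.mtx`` file; ``features.tsv`` and
        ``barcodes.tsv`` sidecars (10x convention, optionally gzipped) must
        sit in the same directory.  For ``dense-csv``/``dense-tsv``, a table
        with identifiers in the header row and first column.
    dialect
        One of ``mtx-triplet``, ``dense-csv``, ``dense-tsv``.
    genes_as_rows
        On-disk orientation of *dense* tables.  The returned matrix always
        has genes as rows.  MTX triplets follow the 10x convention
        (features x barcodes) regardless of this flag.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "mtx-triplet":
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # scipy raises plain ValueError
            raise FormatError(f"not a MatrixMarket file: {path} ({exc})") from exc
        genes = _read_id_column(_find_sidecar(path, ("features", "genes")))
        cells = _read_id_column(_find_sidecar(path, ("barcodes",)))
        dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        return CountMatrix(dense, genes, cells)
    if dialect in ("dense-csv", "dense-tsv"):
        sep = "," if dialect == "dense-csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if not genes_as_rows:
            df = df.T
        return CountMatrix(df.to_numpy(), [str(i) for i in df.index],
                           [str(c) for c in df.columns])
    raise ParameterError(f"unknown counts dialect: {dialect!r}")


def write_counts(counts: CountMatrix, path: str | Path,
                 dialect: str = "mtx-triplet") -> None:
    """Write a count matrix in one of the supported dialects."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "mtx-triplet":
        sparse = scipy.sparse.coo_matrix(counts.values)
        scipy.io.mmwrite(str(path), sparse, field="integer")
        (path.parent / "features.tsv").write_text(
            "".join(f"{g}\n" for g in counts.gene_ids))
        (path.parent / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in counts.cell_ids))
        return
    if dialect in ("dense-csv", "dense-tsv"):
        sep = "," if dialect == "dense-csv" else "\t"
        df = pd.DataFrame(counts.values, index=counts.gene_ids,
                          columns=counts.cell_ids)
        df.to_csv(path, sep=sep)
        return
    raise ParameterError(f"unknown counts dialect: {dialect!r}")


def read_pseudotime(path: str | Path) -> PseudotimeAssignment:
    """Read a two-column (cell_id, time) delimited file; header auto-detected."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    cells: list[str] = []
    times: list[float] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh):
            line = raw.strip()
            if not line:
                continue
            sep = "\t" if "\t" in line else ","
            parts = [f.strip() for f in line.split(sep)]
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno + 1}: expected two columns")
            try:
                t = float(parts[1])
            except ValueError:
                if lineno == 0:  # header row
                    continue
                raise DataError(
                    f"{path}:{lineno + 1}: non-numeric pseudotime {parts[1]!r}")
            if not np.isfinite(t):
                raise DataError(f"{path}:{lineno + 1}: non-finite pseudotime")
            if t < 0:
                raise DataError(f"{path}:{lineno + 1}: negative pseudotime {t}")
            cells.append(parts[0])
            times.append(t)
    return PseudotimeAssignment(cells, np.array(times))


def write_pseudotime(pt: PseudotimeAssignment, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt") as fh:
        fh.write("cell,pseudotime\n")
        for c, t in zip(pt.cell_ids, pt.times):
            fh.write(f"{c},{float(t)!r}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member [TAB member ...]."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno + 1}: GMT line needs >=3 tab-separated fields")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise DataError(f"{path}:{lineno + 1}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for m in parts[2:]:
                if m and m not in seen:
                    members.append(m)
                    seen.add(m)
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_matrix(matrix: np.ndarray, gene_ids: list[str], path: str | Path,
                 fmt: str = "dense-csv", precision: int = 10) -> None:
    """Persist a p x p gene-gene matrix (adjacency or slope matrix).

    ``precision`` is significant digits for the dense-CSV representation;
    the MatrixMarket writer uses repr-exact floats.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(gene_ids) or matrix.shape[1] != len(gene_ids):
        raise ParameterError("gene_ids length must match matrix dimension")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "dense-csv":
        df = pd.DataFrame(matrix, index=gene_ids, columns=gene_ids)
        df.to_csv(path, float_format=f"%.{precision}g")
        return
    if fmt == "mtx-triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix),
                         precision=precision)
        (path.parent / "features.tsv").write_text(
            "".join(f"{g}\n" for g in gene_ids))
        return
    raise ParameterError(f"unknown matrix format: {fmt!r}")


def read_matrix(path: str | Path, fmt: str = "dense-csv") -> tuple[np.ndarray, list[str]]:
    """Load a p x p matrix written by :func:`write_matrix`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt == "dense-csv":
        df = pd.read_csv(path, index_col=0)
        return df.to_numpy(dtype=float), [str(i) for i in df.index]
    if fmt == "mtx-triplet":
        mat = scipy.io.mmread(str(path))
        dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        genes = _read_id_column(_find_sidecar(path, ("features", "genes")))
        return dense.astype(float), genes
    raise ParameterError(f"unknown matrix format: {fmt!r}")
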
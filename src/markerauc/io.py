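"""Readers and writers for every on-disk artifact the pipeline touches.

Count matrices come in either as a MatrixMarket triplet (10x dialect:
genes × cells on disk, transposed to cells × genes in memory) or as a
dense delimited table. Cell annotations, gene sets (GMT or two-column
TSV), per-gene LOEUF constraint tables and AUC tables are plain TSV.

No QC, normalization or batch correction happens at read time: readers
validate shape and value constraints and normalize gene symbols, nothing
else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger("markerauc")

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "GeneSet",
    "ConstraintTable",
    "normalize_symbol",
    "read_counts",
    "read_counts_mtx",
    "read_counts_dense",
    "write_counts_mtx",
    "read_cell_annotation",
    "read_gene_sets",
    "write_gene_sets_gmt",
    "read_constraint_table",
    "write_constraint_table",
    "read_auc_table",
    "write_auc_table",
]


def normalize_symbol(symbol: str) -> str:
    """Case-normalize a gene symbol (strip whitespace, upper-case).

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Cells × genes matrix of raw, non-negative integer counts.

    Parameters
    ----------
    counts
        Sparse CSR matrix, one row per cell, one column per gene.
    cell_ids
        Ordered unique cell barcodes/identifiers.
    gene_ids
        Ordered unique gene symbols (case-normalized).
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [normalize_symbol(g) for g in self.gene_ids]
        n_cells, n_genes = self.counts.shape
        if n_cells == 0 or n_genes == 0:
            raise ValueError("empty expression matrix")
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} cells but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} genes but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(
                "duplicate gene symbols after normalization; collapse before "
                "constructing ExpressionMatrix"
            )
        data = self.counts.data
        if data.size and data.min() < 0:
            raise ValueError("negative counts")
        if np.issubdtype(data.dtype, np.floating):
            if data.size and np.any(data != np.floor(data)):
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class CellAnnotation:
    """Per-cell labels at one or more named hierarchy levels.

    ``labels`` is indexed by cell id with one column per level (e.g.
    class / subclass / cluster). Missing labels are allowed at read time
    and are dropped, with a logged count, when a level is actually used.
    """

    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = pd.DataFrame(self.labels)
        self.labels.index = self.labels.index.astype(str)
        if self.labels.index.has_duplicates:
            dups = self.labels.index[self.labels.index.duplicated()].unique()
            raise ValueError(f"duplicated cell ids in annotation: {list(dups)[:5]}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def levels(self) -> list[str]:
        return list(self.labels.columns)

    def labels_for(self, level: str) -> pd.Series:
        if level not in self.labels.columns:
            raise KeyError(f"annotation has no level {level!r}; levels: {self.levels}")
        return self.labels[level]


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of case-normalized gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(normalize_symbol(g) for g in self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ConstraintTable:
    """Gene symbol → LOEUF map (loss-of-function constraint; lower = more constrained)."""

    loeuf: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.loeuf, dtype=float)
        s.index = [normalize_symbol(g) for g in s.index]
        if s.index.has_duplicates:
            raise ValueError("duplicate gene symbols in constraint table")
        if not np.all(np.isfinite(s.to_numpy())):
            raise ValueError("non-finite LOEUF values")
        if (s < 0).any():
            raise ValueError("negative LOEUF values")
        self.loeuf = s

    def __len__(self) -> int:
        return len(self.loeuf)

    def get(self, gene: str) -> float | None:
        gene = normalize_symbol(gene)
        return float(self.loeuf[gene]) if gene in self.loeuf.index else None


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(
    counts: sp.csr_matrix, gene_ids: list[str]
) -> tuple[sp.csr_matrix, list[str]]:
    """Keep, per duplicated symbol, the column with the highest total count."""
    symbols = [normalize_symbol(g) for g in gene_ids]
    if len(set(symbols)) == len(symbols):
        return counts, symbols
    totals = np.asarray(counts.sum(axis=0)).ravel()
    best: dict[str, int] = {}
    for j, sym in enumerate(symbols):
        if sym not in best or totals[j] > totals[best[sym]]:
            best[sym] = j
    keep = sorted(best.values())
    n_dropped = len(symbols) - len(keep)
    log.warning(
        "collapsed %d duplicate gene symbol(s); kept the copy with the highest total count",
        n_dropped,
    )
    return counts[:, keep].tocsr(), [symbols[j] for j in keep]


def read_counts_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket triplet (genes × cells on disk)."""
    m = sp.csr_matrix(mmread(str(matrix_path)))
    genes_df = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    # 10x genes.tsv may carry (gene_id, symbol); the symbol is the last column
    genes = genes_df.iloc[:, -1].tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
    if m.shape[0] != len(genes):
        raise ValueError(
            f"matrix has {m.shape[0]} gene rows but genes file has {len(genes)} entries"
        )
    if m.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {m.shape[1]} cell columns but barcodes file has {len(barcodes)} entries"
        )
    counts = m.T.tocsr()  # to cells × genes
    counts, genes = _collapse_duplicate_genes(counts, genes)
    return ExpressionMatrix(counts=counts, cell_ids=barcodes, gene_ids=genes)


def read_counts_dense(
    path: str | Path, *, cells_in_rows: bool = True, sep: str | None = None
) -> ExpressionMatrix:
    """Read a dense delimited count table with header row and id column.

    Cells are assumed in rows; pass ``cells_in_rows=False`` for the
    transposed orientation.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"empty count table: {path}")
    if not cells_in_rows:
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("non-numeric entries in count table")
    counts = sp.csr_matrix(values)
    counts, genes = _collapse_duplicate_genes(counts, [str(g) for g in df.columns])
    return ExpressionMatrix(counts=counts, cell_ids=[str(c) for c in df.index], gene_ids=genes)


def read_counts(
    path: str | Path,
    *,
    fmt: str | None = None,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    cells_in_rows: bool = True,
) -> ExpressionMatrix:
    """Dispatching count reader.

    ``fmt`` is ``"mtx"`` or ``"dense"``; if omitted it is inferred from
    the suffix (``.mtx`` → triplet, needs ``genes_path``/``barcodes_path``
    or a sibling ``genes.tsv``/``barcodes.tsv``) or from ``path`` being a
    directory containing ``matrix.mtx``.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir() or path.suffix.lower() == ".mtx":
            fmt = "mtx"
        else:
            fmt = "dense"
    if fmt == "mtx":
        if path.is_dir():
            matrix_path = path / "matrix.mtx"
            genes_path = genes_path or _first_existing(path, ["genes.tsv", "features.tsv"])
            barcodes_path = barcodes_path or path / "barcodes.tsv"
        else:
            matrix_path = path
            genes_path = genes_path or path.with_name("genes.tsv")
            barcodes_path = barcodes_path or path.with_name("barcodes.tsv")
        return read_counts_mtx(matrix_path, genes_path, barcodes_path)
    if fmt == "dense":
        return read_counts_dense(path, cells_in_rows=cells_in_rows)
    raise ValueError(f"unknown count format {fmt!r}")


def _first_existing(directory: Path, names: Sequence[str]) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found in {directory}")


def write_counts_mtx(matrix: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write a matrix as a 10x-style triplet (genes × cells on disk)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_dir / "matrix.mtx"), matrix.counts.T.tocoo(), field="integer")
    (out_dir / "genes.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    (out_dir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in matrix.cell_ids))


# ---------------------------------------------------------------------------
# Cell annotations
# ---------------------------------------------------------------------------


def read_cell_annotation(
    path: str | Path,
    *,
    cell_column: str | None = None,
    level_columns: Sequence[str] | None = None,
    sep: str = "\t",
) -> CellAnnotation:
    """Read a per-cell label table.

    ``cell_column`` defaults to the first column; ``level_columns``
    default to every remaining column. A level with a single distinct
    label is accepted here and rejected only when AUCs are requested for
    it.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"empty annotation table: {path}")
    if cell_column is None:
        cell_column = df.columns[0]
    if cell_column not in df.columns:
        raise ValueError(f"cell id column {cell_column!r} not in {list(df.columns)}")
    if level_columns is None:
        level_columns = [c for c in df.columns if c != cell_column]
    missing = [c for c in level_columns if c not in df.columns]
    if missing:
        raise ValueError(f"requested level column(s) absent: {missing}")
    if not level_columns:
        raise ValueError("no hierarchy level columns")
    out = df.set_index(cell_column)[list(level_columns)]
    return CellAnnotation(labels=out)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, genes…) or a
    two-column (set, gene) TSV; the dialect is sniffed from the content
    unless the suffix is ``.gmt``. Overlap between sets is allowed.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty gene-set file: {path}")
    rows = [ln.split("\t") for ln in lines]
    is_gmt = path.suffix.lower() == ".gmt" or any(len(r) != 2 for r in rows)
    if is_gmt:
        sets = []
        for i, r in enumerate(rows):
            if len(r) < 3:
                raise ValueError(f"GMT line {i + 1} has no genes: {lines[i]!r}")
            name, _desc, genes = r[0], r[1], [g for g in r[2:] if g.strip()]
            if not genes:
                raise ValueError(f"GMT line {i + 1} has no genes: {lines[i]!r}")
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
        return sets
    # two-column TSV, optional header
    if [c.strip().lower() for c in rows[0]] == ["set", "gene"]:
        rows = rows[1:]
        if not rows:
            raise ValueError(f"gene-set file has a header but no rows: {path}")
    grouped: dict[str, set[str]] = {}
    order: list[str] = []
    for i, (name, gene) in enumerate(rows):
        if not name.strip() or not gene.strip():
            raise ValueError(f"unparseable gene-set line {i + 1}")
        if name not in grouped:
            grouped[name] = set()
            order.append(name)
        grouped[name].add(gene)
    return [GeneSet(name=name, genes=frozenset(grouped[name])) for name in order]


def write_gene_sets_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# Constraint tables
# ---------------------------------------------------------------------------


def read_constraint_table(path: str | Path, sep: str = "\t") -> ConstraintTable:
    """Read a TSV with columns ``gene`` and ``loeuf`` (case-insensitive,
    extra columns ignored)."""
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "loeuf" not in cols:
        raise ValueError(
            f"constraint table needs 'gene' and 'loeuf' columns, found {list(df.columns)}"
        )
    s = pd.Series(df[cols["loeuf"]].to_numpy(dtype=float), index=df[cols["gene"]].astype(str))
    return ConstraintTable(loeuf=s)


def write_constraint_table(table: ConstraintTable, path: str | Path) -> None:
    df = pd.DataFrame({"gene": table.loeuf.index, "loeuf": table.loeuf.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AUC tables
# ---------------------------------------------------------------------------


def write_auc_table(table, path: str | Path) -> None:
    """Write an :class:`~markerauc.auc.AUCTable` as TSV (genes × types).

    Hierarchy level and per-type cell counts travel in ``#`` comment
    lines so write→read is the identity.
    """
    from .auc import AUCTable  # local import: auc depends on io types

    assert isinstance(table, AUCTable)
    with open(path, "w") as fh:
        fh.write(f"# level: {table.level}\n")
        if table.n_cells_per_type:
            pairs = "\t".join(f"{k}={v}" for k, v in table.n_cells_per_type.items())
            fh.write(f"# n_cells: {pairs}\n")
        table.auc.to_csv(fh, sep="\t", index_label="gene")


def read_auc_table(path: str | Path):
    from .auc import AUCTable

    path = Path(path)
    level = "unknown"
    n_cells: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, ln in enumerate(lines):
        if not ln.startswith("#"):
            body_start = i
            break
        if ln.startswith("# level:"):
            level = ln.split(":", 1)[1].strip()
        elif ln.startswith("# n_cells:"):
            for pair in ln.split(":", 1)[1].split():
                k, v = pair.split("=")
                n_cells[k] = int(v)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
    df.index.name = None  # the writer labels the index column "gene"
    if df.empty:
        raise ValueError(f"empty AUC table: {path}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("AUC value outside [0, 1] on read")
    return AUCTable(auc=df, level=level, n_cells_per_type=n_cells)
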
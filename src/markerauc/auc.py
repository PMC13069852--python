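"""One-vs-rest ROC curves and AUCs per gene × cell type.

The central statistic: for a gene g and a cell type k at some hierarchy
level, sweep a read-count threshold t over the observed values. The
true-positive rate is the fraction of type-k cells expressing g
strictly above t; the false-positive rate is the same fraction among
all other cells. The area under the resulting ROC curve is a
probability-scaled specificity/sensitivity score: 0.5 means the gene's
counts carry no information about membership in k, 1.0 means perfect
separation (every in-type cell exceeds every out-of-type cell).

Two equivalent routes are provided: an explicit threshold sweep with
trapezoidal integration (:func:`roc_curve` + :func:`auc_trapezoid`) and
the rank formula AUC = U / (n_pos * n_neg) with mid-ranks for ties
(:func:`auc_rank`). With thresholds at every distinct observed value
plus a sentinel, and a strict ``>`` predicate, the two coincide exactly;
the table builder uses the rank route, which is sparse-aware (ties at
zero are handled analytically so only nonzero entries are ranked).

AUCs are computed on raw counts by default. Because the statistic is
rank-based it is invariant to any per-gene monotone transform, but not
to per-cell depth scaling; ``normalize_depth=True`` divides each cell's
counts by its total before ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .io import CellAnnotation, ExpressionMatrix, normalize_symbol

log = logging.getLogger("markerauc")

__all__ = [
    "RocCurve",
    "AUCTable",
    "roc_curve",
    "auc_trapezoid",
    "auc_rank",
    "compute_auc_table",
    "detect_genes",
]


@dataclass
class RocCurve:
    """A one-vs-rest ROC curve.

    ``thresholds`` holds the distinct observed values in descending
    order plus a sentinel below the minimum; ``fpr``/``tpr`` have one
    extra leading entry for the (0, 0) anchor (conceptually t = +inf).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if len(self.fpr) != len(self.thresholds) + 1 or len(self.tpr) != len(self.fpr):
            raise ValueError("fpr/tpr must be one longer than thresholds")
        for name, arr in (("fpr", self.fpr), ("tpr", self.tpr)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} outside [0, 1]")
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} not non-decreasing")
        if self.fpr[0] != 0 or self.tpr[0] != 0 or self.fpr[-1] != 1 or self.tpr[-1] != 1:
            raise ValueError("curve must run from (0, 0) to (1, 1)")


def roc_curve(pos_counts, neg_counts) -> RocCurve:
    """Threshold sweep over the pooled distinct values.

    TPR(t) = fraction of ``pos_counts`` strictly greater than t, and
    likewise FPR(t) on ``neg_counts``; thresholds descend over all
    distinct observed values with a final sentinel below the minimum so
    the curve ends at (1, 1).
    """
    pos = np.asarray(pos_counts, dtype=float)
    neg = np.asarray(neg_counts, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    values = np.unique(np.concatenate([pos, neg]))[::-1]  # descending
    thresholds = np.concatenate([values, [values.min() - 1.0]])
    tpr = np.concatenate([[0.0], (pos[:, None] > thresholds[None, :]).mean(axis=0)])
    fpr = np.concatenate([[0.0], (neg[:, None] > thresholds[None, :]).mean(axis=0)])
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under (fpr, tpr)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_rank(pos_counts, neg_counts) -> float:
    """AUC via the rank formula, U / (n_pos * n_neg), with mid-ranks for ties.

    Equals ``auc_trapezoid(roc_curve(pos, neg))`` on every input.
    """
    pos = np.asarray(pos_counts, dtype=float)
    neg = np.asarray(neg_counts, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class AUCTable:
    """Genes × cell-types AUC matrix for one hierarchy level."""

    auc: pd.DataFrame
    level: str = "type"
    n_cells_per_type: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.auc = pd.DataFrame(self.auc).astype(float)
        if self.auc.empty:
            raise ValueError("empty AUC table")
        values = self.auc.to_numpy()
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("AUC values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.auc.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.auc.columns)

    def values_for(self, genes) -> pd.DataFrame:
        """Restrict to a gene subset, silently dropping absent symbols."""
        wanted = [normalize_symbol(g) for g in genes]
        present = [g for g in wanted if g in self.auc.index]
        return self.auc.loc[present]


def _sparse_group_rank_auc(
    counts: sp.csc_matrix, codes: np.ndarray, n_per_type: np.ndarray
) -> np.ndarray:
    """Per-gene one-vs-rest AUC for every type, exploiting zero-majority.

    All zero entries of a gene share the mid-rank (n_zero + 1) / 2;
    nonzero (strictly positive) entries rank above them, so only the
    nonzeros need explicit ranking. Returns a genes × types array.
    """
    n_cells = counts.shape[0]
    n_types = len(n_per_type)
    n_neg = n_cells - n_per_type
    out = np.empty((counts.shape[1], n_types), dtype=float)
    indptr, indices, data = counts.indptr, counts.indices, counts.data
    for j in range(counts.shape[1]):
        rows = indices[indptr[j] : indptr[j + 1]]
        vals = data[indptr[j] : indptr[j + 1]]
        n_nz = len(vals)
        n_zero = n_cells - n_nz
        zero_rank = (n_zero + 1) / 2.0
        if n_nz:
            ranks_nz = n_zero + rankdata(vals)
            grp = codes[rows]
            sum_nz = np.bincount(grp, weights=ranks_nz, minlength=n_types)
            cnt_nz = np.bincount(grp, minlength=n_types)
        else:
            sum_nz = np.zeros(n_types)
            cnt_nz = np.zeros(n_types)
        rank_sum = sum_nz + (n_per_type - cnt_nz) * zero_rank
        u = rank_sum - n_per_type * (n_per_type + 1) / 2.0
        out[j] = u / (n_per_type * n_neg)
    # guard against float round-off at the boundaries
    np.clip(out, 0.0, 1.0, out=out)
    return out


def compute_auc_table(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    level: str,
    genes=None,
    *,
    normalize_depth: bool = False,
) -> AUCTable:
    """Compute the one-vs-rest AUC of every gene for every cell type.

    Parameters
    ----------
    matrix
        Raw counts, cells × genes.
    annotation
        Per-cell labels; cells missing a label at ``level`` are dropped
        (logged). The level must retain at least two distinct labels.
    genes
        Optional gene subset; unknown symbols (after case
        normalization) are reported and skipped.
    normalize_depth
        Divide each cell's counts by its total count before ranking.
        Off by default: the statistic is defined on raw read counts.
    """
    labels_all = annotation.labels_for(level)
    labels = labels_all.reindex(matrix.cell_ids)
    keep = labels.notna().to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropping %d cell(s) without a %r label", n_dropped, level)
    labels = labels[keep]
    cell_idx = np.flatnonzero(keep)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError(f"level {level!r} has {len(types)} label(s); need at least 2")
    codes = labels.map({t: i for i, t in enumerate(types)}).to_numpy(dtype=np.intp)
    n_per_type = np.bincount(codes, minlength=len(types)).astype(float)

    if genes is None:
        gene_ids = list(matrix.gene_ids)
        gene_idx = np.arange(matrix.n_genes)
    else:
        lookup = {g: j for j, g in enumerate(matrix.gene_ids)}
        wanted = [normalize_symbol(g) for g in genes]
        unknown = [g for g in wanted if g not in lookup]
        if unknown:
            log.warning("skipping %d unknown gene symbol(s): %s", len(unknown), unknown[:10])
        gene_ids = [g for g in wanted if g in lookup]
        if not gene_ids:
            raise ValueError("no requested gene present in the matrix")
        gene_idx = np.array([lookup[g] for g in gene_ids])

    sub = matrix.counts[cell_idx][:, gene_idx]
    if normalize_depth:
        totals = np.asarray(matrix.counts[cell_idx].sum(axis=1)).ravel().astype(float)
        totals[totals == 0] = 1.0
        sub = sp.diags(1.0 / totals) @ sub.astype(float)
    sub = sub.tocsc()
    sub.eliminate_zeros()

    auc = _sparse_group_rank_auc(sub, codes, n_per_type)
    df = pd.DataFrame(auc, index=gene_ids, columns=types)
    n_cells = {t: int(n_per_type[i]) for i, t in enumerate(types)}
    return AUCTable(auc=df, level=level, n_cells_per_type=n_cells)


def detect_genes(matrix: ExpressionMatrix, min_cells: int = 1) -> list[str]:
    """Genes with a nonzero count in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    csc = matrix.counts.tocsc()
    csc.eliminate_zeros()
    n_nonzero = np.diff(csc.indptr)
    return [g for g, n in zip(matrix.gene_ids, n_nonzero) if n >= min_cells]
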
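"""Gene taxonomy from an AUC table.

Each gene is summarised by AUC_max, the maximum of its per-type AUCs at
a hierarchy level, and binned into three categories:

- marker:       AUC_max >= 0.8 (quasi-categorical, type-restricted expression)
- intermediate: 0.6 <= AUC_max < 0.8 (preferential / differential expression)
- ubiquitous:   AUC_max < 0.6 (no useful type separation)

Both boundaries follow the inequality conventions above exactly: a gene
at 0.8 is a marker, a gene at 0.6 is intermediate. The module also
counts candidate markers per type, traces the assignment curve (mean
number of types a gene is assigned to as the AUC cutoff rises) and
orders cell types by hierarchical clustering of their marker-AUC
profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .auc import AUCTable

log = logging.getLogger("markerauc")

__all__ = [
    "MARKER_THRESHOLD",
    "UBIQUITOUS_THRESHOLD",
    "GeneClassification",
    "auc_max",
    "classify_genes",
    "classify_table",
    "count_markers_per_type",
    "assignment_curve",
    "cluster_celltypes",
]

MARKER_THRESHOLD = 0.8
UBIQUITOUS_THRESHOLD = 0.6


@dataclass(frozen=True)
class GeneClassification:
    gene: str
    auc_max: float
    best_type: str
    category: str  # marker | intermediate | ubiquitous


def auc_max(table: AUCTable) -> pd.DataFrame:
    """Row-wise maximum AUC and the type attaining it.

    Ties are broken by the first type in table column order; tied genes
    are logged.
    """
    values = table.auc.to_numpy()
    best_idx = values.argmax(axis=1)  # argmax takes the first on ties
    best = values[np.arange(len(values)), best_idx]
    n_tied = int((values == best[:, None]).sum(axis=1).max() > 1) and int(
        ((values == best[:, None]).sum(axis=1) > 1).sum()
    )
    if n_tied:
        log.info("%d gene(s) with tied AUC_max; first type in table order kept", n_tied)
    types = np.array(table.cell_types)
    return pd.DataFrame(
        {"auc_max": best, "best_type": types[best_idx]}, index=table.genes
    )


def _categorize(values: np.ndarray, marker_threshold: float, ubiquitous_threshold: float):
    cats = np.where(
        values >= marker_threshold,
        "marker",
        np.where(values < ubiquitous_threshold, "ubiquitous", "intermediate"),
    )
    return cats


def classify_genes(
    aucmax: pd.DataFrame,
    marker_threshold: float = MARKER_THRESHOLD,
    ubiquitous_threshold: float = UBIQUITOUS_THRESHOLD,
) -> list[GeneClassification]:
    """Three-way partition of genes from their (auc_max, best_type) rows.

    ``aucmax`` is the frame produced by :func:`auc_max`. Boundary
    semantics: ``auc_max >= marker_threshold`` → marker,
    ``auc_max < ubiquitous_threshold`` → ubiquitous, else intermediate.
    """
    if not (0.0 <= ubiquitous_threshold <= marker_threshold <= 1.0):
        raise ValueError(
            "thresholds must satisfy 0 <= ubiquitous <= marker <= 1, got "
            f"{ubiquitous_threshold} / {marker_threshold}"
        )
    values = aucmax["auc_max"].to_numpy(dtype=float)
    cats = _categorize(values, marker_threshold, ubiquitous_threshold)
    return [
        GeneClassification(gene=str(g), auc_max=float(v), best_type=str(t), category=str(c))
        for g, v, t, c in zip(aucmax.index, values, aucmax["best_type"], cats)
    ]


def classify_table(
    table: AUCTable,
    marker_threshold: float = MARKER_THRESHOLD,
    ubiquitous_threshold: float = UBIQUITOUS_THRESHOLD,
) -> pd.DataFrame:
    """Convenience: AUC table → DataFrame(gene, auc_max, best_type, category)."""
    am = auc_max(table)
    cls = classify_genes(am, marker_threshold, ubiquitous_threshold)
    return pd.DataFrame(
        {
            "auc_max": [c.auc_max for c in cls],
            "best_type": [c.best_type for c in cls],
            "category": [c.category for c in cls],
        },
        index=[c.gene for c in cls],
    ).rename_axis("gene")


def count_markers_per_type(
    table: AUCTable, threshold: float = MARKER_THRESHOLD
) -> tuple[pd.Series, float, int]:
    """Candidate-marker counts per cell type.

    A gene counts for type k when AUC(g, k) >= threshold; a gene above
    threshold in several types counts for each of them, but only once in
    the distinct total. Returns (per-type counts, mean per type, total
    distinct markers).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    hits = table.auc.to_numpy() >= threshold
    per_type = pd.Series(hits.sum(axis=0), index=table.cell_types, name="n_markers")
    total_distinct = int(hits.any(axis=1).sum())
    return per_type, float(per_type.mean()), total_distinct


def assignment_curve(
    table: AUCTable,
    cutoffs=None,
    *,
    include_zero_assignment: bool = False,
    aucmax_binned: bool = False,
) -> pd.DataFrame:
    """Mean (± SD) number of cell types a gene is assigned to per AUC cutoff.

    At cutoff x a gene is assigned to every type with AUC(g, k) >= x.
    Genes with no assignment at x are excluded from the mean by default
    (``include_zero_assignment=True`` counts them as 0 instead). The
    alternative ``aucmax_binned`` mode assigns each gene only at its
    AUC_max bin, counting the types whose AUC ties the row maximum.
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.5, 1.0001, 0.05), 10)
    values = table.auc.to_numpy()
    rows = []
    for x in cutoffs:
        if aucmax_binned:
            row_max = values.max(axis=1)
            in_bin = row_max >= x
            n_assigned = (values >= row_max[:, None]).sum(axis=1)[in_bin]
        else:
            n_assigned = (values >= x).sum(axis=1)
        if not include_zero_assignment:
            n_assigned = n_assigned[n_assigned > 0]
        if len(n_assigned):
            mean = float(np.mean(n_assigned))
            sd = float(np.std(n_assigned, ddof=0))
        else:
            mean, sd = np.nan, np.nan
        rows.append({"cutoff": float(x), "mean": mean, "sd": sd, "n_genes": int(len(n_assigned))})
    return pd.DataFrame(rows)


def cluster_celltypes(table: AUCTable) -> tuple[list[str], np.ndarray]:
    """Order cell types by average-linkage hierarchical clustering of
    their AUC profiles over a marker panel (Euclidean distance).

    Returns the leaf-ordered type labels and the scipy linkage matrix.
    Deterministic: no randomness is involved.
    """
    if len(table.cell_types) < 2:
        raise ValueError("need at least 2 cell types to cluster")
    profiles = table.auc.to_numpy().T  # types × genes
    z = linkage(profiles, method="average", metric="euclidean")
    order = leaves_list(z)
    types = np.array(table.cell_types)
    return [str(t) for t in types[order]], z
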
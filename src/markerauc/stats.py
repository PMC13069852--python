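"""Gene-set statistics on AUC_max distributions.

Compares the cell-type specificity of named gene sets (e.g. syndromic
vs non-syndromic disease genes vs candidate markers) via two-sided
Mann–Whitney U tests with median differences, builds an empirical
random-gene resampling null for a set-level statistic, and summarises
loss-of-function constraint (LOEUF) per set.

Genes of a set that are absent from the AUC table (undetected in the
dataset) are dropped before testing, with the matched count reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import ConstraintTable, GeneSet, normalize_symbol

log = logging.getLogger("markerauc")

__all__ = [
    "ComparisonResult",
    "ResampleResult",
    "ConstraintSummary",
    "compare_sets_mannwhitney",
    "pairwise_compare",
    "resample_null",
    "constraint_summary",
    "cross_dataset_consistency",
    "aucmax_for_set",
]

EXACT_MAX_PRODUCT = 1_000  # exact enumeration when n_a * n_b <= this and no ties


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided Mann–Whitney comparison of two AUC_max samples."""

    set_a: str
    set_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_two_sided: float
    median_diff: float  # median(a) - median(b)

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_two_sided))


@dataclass(frozen=True)
class ResampleResult:
    """Empirical one-sided random-gene null for a set statistic."""

    observed_stat: float
    null_stats: np.ndarray
    p_empirical: float
    B: int
    seed: int
    statistic: str


@dataclass(frozen=True)
class ConstraintSummary:
    set_name: str
    median_loeuf: float
    fraction_above_threshold: float
    n_matched: int
    n_unmatched: int
    threshold: float


def compare_sets_mannwhitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    name_a: str = "A",
    name_b: str = "B",
) -> ComparisonResult:
    """Two-sided Mann–Whitney U with mid-rank tie handling.

    The p value is exact (enumeration) when ``n_a * n_b <= 1000`` and
    the pooled sample is tie-free; otherwise a normal approximation with
    tie-corrected variance and continuity correction is used. When every
    pooled value is identical the variance is zero and p = 1 by
    convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    median_diff = float(np.median(a) - np.median(b))
    if np.ptp(pooled) == 0.0:
        return ComparisonResult(
            set_a=name_a, set_b=name_b, n_a=a.size, n_b=b.size,
            u_statistic=a.size * b.size / 2.0, p_two_sided=1.0, median_diff=0.0,
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= EXACT_MAX_PRODUCT and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        set_a=name_a, set_b=name_b, n_a=int(a.size), n_b=int(b.size),
        u_statistic=float(res.statistic), p_two_sided=p, median_diff=median_diff,
    )


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pairwise_compare(
    sets: Mapping[str, Sequence[float]], adjust: str = "none"
) -> pd.DataFrame:
    """All ordered-pair Mann–Whitney comparisons between named samples.

    Returns a long-form frame with U, two-sided p, -log10(p), the median
    difference (antisymmetric in the pair order), and significance stars
    (* p < 0.05, ** p < 0.01). ``adjust="bh"`` adds Benjamini–Hochberg
    q values computed across the unordered pairs.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    for name in names:
        if len(sets[name]) == 0:
            raise ValueError(f"set {name!r} is empty")
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    unordered = list(combinations(names, 2))
    results = {
        (a, b): compare_sets_mannwhitney(sets[a], sets[b], a, b) for a, b in unordered
    }
    qmap: dict[tuple[str, str], float] = {}
    if adjust == "bh":
        ps = [results[pair].p_two_sided for pair in unordered]
        q = multipletests(ps, method="fdr_bh")[1]
        qmap = dict(zip(unordered, q))
    rows = []
    for a, b in unordered:
        r = results[(a, b)]
        for sa, sb, md, u in (
            (a, b, r.median_diff, r.u_statistic),
            (b, a, -r.median_diff, r.n_a * r.n_b - r.u_statistic),
        ):
            row = {
                "set_a": sa, "set_b": sb,
                "n_a": len(sets[sa]), "n_b": len(sets[sb]),
                "u_statistic": u, "p_two_sided": r.p_two_sided,
                "neg_log10_p": r.neg_log10_p, "median_diff": md,
                "stars": _stars(r.p_two_sided),
            }
            if adjust == "bh":
                row["q_bh"] = qmap[(a, b)]
            rows.append(row)
    return pd.DataFrame(rows)


def resample_null(
    target_values: Sequence[float],
    universe_values: Sequence[float],
    set_size: int | None = None,
    B: int = 9_999,
    seed: int = 0,
    statistic: str = "median",
    *,
    exhaustive: bool = False,
) -> ResampleResult:
    """Random-gene resampling null for a set-level statistic.

    Draws ``B`` gene subsets of size ``set_size`` without replacement
    from the universe (all detected genes), computes ``statistic``
    (median or mean of AUC_max) for each, and reports the one-sided
    (greater) empirical p with add-one correction:
    ``p = (1 + #{null >= observed}) / (B + 1)``, so p is never exactly 0.

    ``exhaustive=True`` replaces the random draws by enumeration of
    every subset (tiny universes only).
    """
    target = np.asarray(target_values, dtype=float)
    universe = np.asarray(universe_values, dtype=float)
    if target.size == 0:
        raise ValueError("empty target set")
    n = target.size if set_size is None else int(set_size)
    if n < 1:
        raise ValueError("set_size must be >= 1")
    if n > universe.size:
        raise ValueError(f"set_size {n} exceeds universe size {universe.size}")
    stat_fn = {"median": np.median, "mean": np.mean}.get(statistic)
    if stat_fn is None:
        raise ValueError(f"unknown statistic {statistic!r}")
    observed = float(stat_fn(target))
    if exhaustive:
        null = np.array(
            [stat_fn(universe[list(idx)]) for idx in combinations(range(universe.size), n)]
        )
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        # one key matrix -> top-n per row = a uniform subset; independent of
        # iteration order by construction
        keys = rng.random((B, universe.size))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        null = stat_fn(universe[idx], axis=1)
    b_eff = int(null.size)
    p = float((1 + int(np.sum(null >= observed))) / (b_eff + 1))
    return ResampleResult(
        observed_stat=observed, null_stats=null, p_empirical=p, B=b_eff,
        seed=int(seed), statistic=statistic,
    )


def constraint_summary(
    gene_set: GeneSet, table: ConstraintTable, constraint_threshold: float = 0.6
) -> ConstraintSummary:
    """Median LOEUF of a gene set and the fraction strictly above the
    constraint limit (LOEUF > threshold means tolerant to loss of
    function). Genes absent from the table are counted and reported.
    """
    matched = [g for g in gene_set.genes if g in table.loeuf.index]
    n_unmatched = len(gene_set) - len(matched)
    if n_unmatched:
        log.info("set %s: %d gene(s) missing from constraint table", gene_set.name, n_unmatched)
    if not matched:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the constraint table")
    values = table.loeuf.loc[matched].to_numpy()
    return ConstraintSummary(
        set_name=gene_set.name,
        median_loeuf=float(np.median(values)),
        fraction_above_threshold=float(np.mean(values > constraint_threshold)),
        n_matched=len(matched),
        n_unmatched=n_unmatched,
        threshold=float(constraint_threshold),
    )


def cross_dataset_consistency(
    aucmax_by_dataset: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> dict[str, ComparisonResult]:
    """Per-set two-sided Mann–Whitney between two datasets' AUC_max values.

    ``aucmax_by_dataset`` maps a set name to its (dataset-1, dataset-2)
    AUC_max samples. A non-significant result means the set's
    specificity profile replicates across datasets.
    """
    out = {}
    for name, pair in aucmax_by_dataset.items():
        if len(pair) != 2:
            raise ValueError(f"set {name!r}: expected values for exactly 2 datasets")
        v1, v2 = pair
        if len(v1) == 0 or len(v2) == 0:
            raise ValueError(f"set {name!r} missing from one dataset")
        out[name] = compare_sets_mannwhitney(v1, v2, f"{name}@ds1", f"{name}@ds2")
    return out


def aucmax_for_set(aucmax: pd.Series, gene_set: GeneSet) -> np.ndarray:
    """AUC_max values of the set's detected members.

    ``aucmax`` is indexed by gene symbol (e.g. the ``auc_max`` column of
    :func:`markerauc.classify.classify_table`). Undetected members are
    dropped with a logged count.
    """
    wanted = {normalize_symbol(g) for g in gene_set.genes}
    present = [g for g in aucmax.index if g in wanted]
    n_missing = len(wanted) - len(present)
    if n_missing:
        log.info("set %s: %d gene(s) not detected, dropped", gene_set.name, n_missing)
    return aucmax.loc[present].to_numpy(dtype=float)
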
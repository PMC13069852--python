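"""Synthetic labeled single-cell count data with planted gene roles.

Emulates the statistical structure the AUC framework responds to: a
cells × genes matrix where each gene is one of

- marker:     high mean in exactly one target type, near-zero elsewhere
              (defaults 10 vs 0.1);
- de:         basal mean everywhere plus a fold enrichment in 1–3
              target types (defaults: baseline 1, fold 4);
- ubiquitous: the same mean in every type (default 2).

Counts are negative binomial with a common dispersion (size) parameter,
the standard overdispersed model for scRNA-seq UMI counts, times a
per-cell depth factor drawn log-uniformly (default [0.5, 2]) so that
sequencing-depth effects — the one nuisance the rank-based AUC is *not*
automatically invariant to — are present. ``dispersion=None`` gives the
Poisson limit.

Everything is a pure function of (config, seed): identical inputs give
bit-for-bit identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellAnnotation, ConstraintTable, ExpressionMatrix, GeneSet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "simulate_gene_sets",
    "simulate_constraint_table",
    "DEFAULT_LOEUF_DISTRIBUTIONS",
]


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    All means are per-cell expected counts before depth scaling;
    ``dispersion`` is the negative-binomial size parameter r (variance
    mu + mu^2 / r), with ``None`` meaning the Poisson limit.
    ``hierarchy`` optionally groups type labels into named classes,
    adding a second annotation level.
    """

    n_types: int = 4
    cells_per_type: int = 200
    n_marker: int = 40
    n_de: int = 40
    n_ubiquitous: int = 100
    marker_mean_in: float = 10.0
    marker_mean_out: float = 0.1
    de_baseline_mean: float = 1.0
    de_fold: float = 4.0
    ubiq_mean: float = 2.0
    dispersion: float | None = 1.0
    depth_range: tuple[float, float] = (0.5, 2.0)
    hierarchy: Mapping[str, Sequence[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("n_types must be >= 2")
        if self.cells_per_type < 10:
            raise ValueError("cells_per_type must be >= 10")
        for name in ("n_marker", "n_de", "n_ubiquitous"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_marker + self.n_de + self.n_ubiquitous == 0:
            raise ValueError("no genes requested")
        for name in (
            "marker_mean_in", "marker_mean_out", "de_baseline_mean", "de_fold", "ubiq_mean"
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (or None for Poisson)")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must be a positive interval")

    @property
    def type_labels(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_types)]


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth for one simulated gene."""

    gene: str
    role: str  # marker | de | ubiquitous
    target_types: frozenset[str]
    effect: tuple[float, float]  # (mean in targets, mean elsewhere)

    def __post_init__(self) -> None:
        if self.role == "marker" and len(self.target_types) != 1:
            raise ValueError("marker must have exactly 1 target type")
        if self.role == "de" and not (1 <= len(self.target_types) <= 3):
            raise ValueError("de gene must have 1-3 target types")
        if self.role == "ubiquitous" and self.target_types:
            raise ValueError("ubiquitous gene has no target types")


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float | None):
    if dispersion is None:
        return rng.poisson(mean)
    r = float(dispersion)
    return rng.negative_binomial(r, r / (r + mean))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, list[SimulationTruth]]:
    """Generate (counts, annotation, truth) under the planted-role model.

    Gene order is markers (target types assigned round-robin), then DE
    genes (1-3 random target types each), then ubiquitous genes; names
    are G0001…, cells C000001… grouped by type, types T01….
    """
    rng = np.random.default_rng(config.seed)
    types = config.type_labels
    n_cells = config.n_types * config.cells_per_type
    cell_ids = [f"C{i + 1:06d}" for i in range(n_cells)]
    type_codes = np.repeat(np.arange(config.n_types), config.cells_per_type)

    lo, hi = config.depth_range
    depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cells))

    truths: list[SimulationTruth] = []
    mu_by_type: list[np.ndarray] = []  # per gene: length-n_types mean vector
    gene_counter = 0

    def next_name() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"G{gene_counter:04d}"

    for i in range(config.n_marker):
        target = i % config.n_types
        mu = np.full(config.n_types, config.marker_mean_out)
        mu[target] = config.marker_mean_in
        truths.append(
            SimulationTruth(
                gene=next_name(), role="marker",
                target_types=frozenset({types[target]}),
                effect=(config.marker_mean_in, config.marker_mean_out),
            )
        )
        mu_by_type.append(mu)

    for _ in range(config.n_de):
        k = int(rng.integers(1, 4))
        k = min(k, config.n_types - 1)  # keep at least one non-target type
        targets = rng.choice(config.n_types, size=k, replace=False)
        mu = np.full(config.n_types, config.de_baseline_mean)
        mu[targets] = config.de_baseline_mean * config.de_fold
        truths.append(
            SimulationTruth(
                gene=next_name(), role="de",
                target_types=frozenset(types[t] for t in targets),
                effect=(config.de_baseline_mean * config.de_fold, config.de_baseline_mean),
            )
        )
        mu_by_type.append(mu)

    for _ in range(config.n_ubiquitous):
        mu = np.full(config.n_types, config.ubiq_mean)
        truths.append(
            SimulationTruth(
                gene=next_name(), role="ubiquitous", target_types=frozenset(),
                effect=(config.ubiq_mean, config.ubiq_mean),
            )
        )
        mu_by_type.append(mu)

    mu_matrix = np.stack(mu_by_type, axis=1)  # n_types × n_genes
    mean = depth[:, None] * mu_matrix[type_codes]  # n_cells × n_genes
    counts = _draw_counts(rng, mean, config.dispersion).astype(np.int64)

    gene_ids = [t.gene for t in truths]
    matrix = ExpressionMatrix(counts=sp.csr_matrix(counts), cell_ids=cell_ids, gene_ids=gene_ids)

    labels = pd.DataFrame({"type": [types[c] for c in type_codes]}, index=cell_ids)
    if config.hierarchy is not None:
        type_to_class: dict[str, str] = {}
        for cls, members in config.hierarchy.items():
            for t in members:
                type_to_class[t] = cls
        missing = [t for t in types if t not in type_to_class]
        if missing:
            raise ValueError(f"hierarchy does not cover type(s) {missing}")
        labels["class"] = labels["type"].map(type_to_class)
    annotation = CellAnnotation(labels=labels)
    return matrix, annotation, truths


def simulate_gene_sets(
    truth: Sequence[SimulationTruth],
    scheme: Mapping[str, Mapping[str, int]],
    seed: int = 0,
) -> list[GeneSet]:
    """Build gene sets of controlled role composition.

    ``scheme`` maps a set name to role → count, e.g.
    ``{"marker_rich": {"marker": 30, "de": 5}, "low_specificity":
    {"ubiquitous": 40}}``. Members are drawn without replacement within
    each set (sets may overlap each other). Raises if a role is
    over-requested.
    """
    if not truth:
        raise ValueError("empty truth list")
    if not scheme:
        raise ValueError("empty scheme")
    by_role: dict[str, list[str]] = {"marker": [], "de": [], "ubiquitous": []}
    for t in truth:
        by_role[t.role].append(t.gene)
    rng = np.random.default_rng(seed)
    sets = []
    for name, composition in scheme.items():
        genes: list[str] = []
        for role, n in composition.items():
            if role not in by_role:
                raise ValueError(f"unknown role {role!r} in scheme for set {name!r}")
            pool = by_role[role]
            if n > len(pool):
                raise ValueError(
                    f"set {name!r} requests {n} {role} genes but only {len(pool)} exist"
                )
            genes.extend(rng.choice(pool, size=n, replace=False))
        sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


# Default LOEUF generators per planted role: markers are, on average, the
# least constrained (most of their mass above the 0.6 limit), ubiquitous
# genes the most constrained — the direction constraint_summary should
# separate. Purely synthetic; not fit to any constraint release.
DEFAULT_LOEUF_DISTRIBUTIONS: dict[str, tuple] = {
    "marker": ("uniform", 0.2, 1.1),
    "de": ("uniform", 0.1, 0.9),
    "ubiquitous": ("uniform", 0.05, 0.7),
}


def _draw_loeuf(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    kind = spec[0]
    if kind == "point":
        return np.full(size, float(spec[1]))
    if kind == "uniform":
        return rng.uniform(float(spec[1]), float(spec[2]), size=size)
    if kind == "normal":
        return np.clip(rng.normal(float(spec[1]), float(spec[2]), size=size), 0.0, None)
    raise ValueError(f"unknown LOEUF distribution kind {spec[0]!r}")


def simulate_constraint_table(
    truth: Sequence[SimulationTruth],
    association: Mapping[str, tuple] | None = None,
    seed: int = 0,
) -> ConstraintTable:
    """One LOEUF value per simulated gene, drawn from its role's
    distribution (``("point", v)``, ``("uniform", lo, hi)`` or
    ``("normal", mean, sd)``; defaults in
    :data:`DEFAULT_LOEUF_DISTRIBUTIONS`). Seeded and reproducible.
    """
    assoc = dict(DEFAULT_LOEUF_DISTRIBUTIONS)
    if association:
        assoc.update(association)
    rng = np.random.default_rng(seed)
    values = np.empty(len(truth))
    for role in ("marker", "de", "ubiquitous"):
        idx = [i for i, t in enumerate(truth) if t.role == role]
        if idx:
            values[idx] = _draw_loeuf(rng, assoc[role], len(idx))
    return ConstraintTable(loeuf=pd.Series(values, index=[t.gene for t in truth]))
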
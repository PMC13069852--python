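# markerauc

Quantifying the cell-type specificity *and* sensitivity of genes from
labeled single-cell RNA-seq count data, using one-vs-rest ROC/AUC
scoring, with downstream marker classification and gene-set statistics.

## The problem

Single-cell atlases organize brain (and other) cell types into
hierarchies of classes, subclasses and clusters, but most
differential-expression tools only ask whether a gene is *enriched* in
a type — they do not quantify how well its expression *discriminates*
that type. Genes span a continuum from markers (quasi-categorical
expression in one population) through preferentially/differentially
expressed (DE) genes to ubiquitous housekeeping genes, and placing
disease-associated genes on this continuum matters for predicting which
cell types their disruption will affect.

## The statistic

For gene *g* and cell type *k* at a hierarchy level, sweep a read-count
threshold *t* over the observed counts:

- TPR(*t*) = fraction of type-*k* cells with count(*g*) > *t*  (sensitivity)
- FPR(*t*) = fraction of all other cells with count(*g*) > *t*  (1 − specificity)

The ROC curve traces (FPR, TPR) over all thresholds; its area,

AUC(*g*, *k*) = P(X<sub>in</sub> > X<sub>out</sub>) + ½ P(X<sub>in</sub> = X<sub>out</sub>),

equals the Mann–Whitney U statistic scaled to [0, 1] (mid-ranks for
ties). AUC = 0.5 means no separation; AUC = 1 means every in-type cell
exceeds every out-of-type cell. Per gene, AUC_max = max<sub>k</sub>
AUC(*g*, *k*) summarizes specificity at that level, and genes are
binned:

| category     | rule                  |
|--------------|-----------------------|
| marker       | AUC_max ≥ 0.8         |
| intermediate | 0.6 ≤ AUC_max < 0.8   |
| ubiquitous   | AUC_max < 0.6         |

Downstream, gene sets (e.g. disease-gene lists) are compared on their
AUC_max distributions with two-sided Mann–Whitney U tests and median
differences, against a random-gene resampling null, and annotated with
loss-of-function constraint (LOEUF, constraint limit 0.6).

Because real atlases are large downloads, the package ships a seeded
negative-binomial simulator that plants marker / DE / ubiquitous genes
with known ground truth, so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from markerauc import (SimulationConfig, simulate_dataset, compute_auc_table,
                       classify_table, count_markers_per_type,
                       compare_sets_mannwhitney, resample_null)

config = SimulationConfig(seed=1)          # 4 types x 200 cells, 180 genes
matrix, annotation, truth = simulate_dataset(config)
table = compute_auc_table(matrix, annotation, "type")
cls = classify_table(table)                # AUC_max, best type, category

print(cls["category"].value_counts().to_string())
per_type, mean_per_type, total = count_markers_per_type(table)
print(f"markers per type: {per_type.to_list()}  (mean {mean_per_type:.1f}, {total} distinct)")

markers = cls.index[cls.category == "marker"]
ubiq = [t.gene for t in truth if t.role == "ubiquitous"]
r = compare_sets_mannwhitney(cls.loc[markers, "auc_max"], cls.loc[ubiq, "auc_max"])
print(f"marker vs ubiquitous AUC_max: U={r.u_statistic:.0f}, "
      f"p={r.p_two_sided:.2e}, median diff={r.median_diff:.3f}")

res = resample_null(cls.loc[markers, "auc_max"], cls["auc_max"].to_numpy(),
                    B=9999, seed=1)
print(f"random-gene null: observed median {res.observed_stat:.3f}, "
      f"empirical p = {res.p_empirical:.1e}")
```

Output:

```
category
ubiquitous      106
marker           40
intermediate     34
markers per type: [10, 10, 10, 10]  (mean 10.0, 40 distinct)
marker vs ubiquitous AUC_max: U=4000, p=2.89e-20, median diff=0.419
random-gene null: observed median 0.945, empirical p = 1.0e-04
```

All 40 planted markers are recovered, 10 per type; the marker set's
AUC_max distribution separates sharply from the ubiquitous genes
(U = n<sub>a</sub>·n<sub>b</sub>, the maximum), and the marker set's
median AUC_max (0.945) exceeds every one of 9,999 random same-size gene
draws (the add-one empirical p floor of 1/10,000).

## Command line

The same pipeline runs from a shell; every stage is deterministic given
`--seed` and writes a manifest with versions and input checksums:

```bash
markerauc --seed 1 --out-dir run simulate
markerauc --out-dir run auc --counts run/matrix.mtx --genes-file run/genes.tsv \
    --barcodes run/barcodes.tsv --cells run/cells.tsv --level type --out run/auc.tsv
markerauc --out-dir run classify --auc-table run/auc.tsv --out-prefix run/
markerauc --seed 1 --out-dir run compare --auc-table run/auc.tsv \
    --gene-sets run/gene_sets.gmt --constraint-table run/constraint.tsv --out-prefix run/
```

Real data drops in the same way: a 10x-style MTX triplet or dense
CSV/TSV of counts, a cell-annotation TSV, gene sets in GMT or
two-column TSV, and a `gene`/`loeuf` constraint TSV.

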
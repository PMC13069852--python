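# Methods

## The AUC statistic

For a gene *g* and cell type *k* at one annotation level, the cells are
split one-vs-rest: the positives are the cells labeled *k*, the
negatives are all other labeled cells at that level. Sweeping a
read-count threshold *t* (strictly greater: a cell "expresses above
*t*" when count > *t*) over every distinct observed value plus a
sentinel below the minimum yields TPR(*t*) and FPR(*t*); the ROC curve
is anchored at (0, 0) and (1, 1) and the AUC is its trapezoidal area.

With this exact threshold set and the strict predicate, the trapezoidal
area coincides with the rank formula

AUC = U / (n_pos · n_neg),  U = R_pos − n_pos(n_pos + 1)/2,

where R_pos is the positives' rank sum with mid-ranks for ties. Both
routes are implemented (`roc_curve`/`auc_trapezoid` and `auc_rank`) and
their equality is a tested property (1e-12 on tie-heavy random
instances); the table builder uses the rank route.

Counts are used raw. Rank invariance makes any per-gene monotone
normalization (CPM scaling, log1p) irrelevant, but per-cell depth
scaling is *not* a per-gene monotone map and can change results, so an
optional `normalize_depth` flag divides each cell by its total count
before ranking. Default off: the statistic is defined directly on read
counts.

Sparse-aware evaluation: in a zero-dominated column all zeros share the
mid-rank (n_zero + 1)/2, so only nonzero entries are explicitly ranked
and per-type rank sums come from bincounts over the nonzero rows. Cost
is O(nnz log nnz) per gene, independent of the number of types, which
keeps ~100k-cell matrices tractable on one CPU. Final values are
clipped to [0, 1] to absorb float round-off at the boundaries.

Gene detection uses "nonzero in ≥ 1 cell" by default (`min_cells`
configurable). Cells without a label at the requested level are
dropped, with a logged count; a level needs ≥ 2 distinct labels.

## Gene taxonomy

AUC_max is the row-wise maximum over types (ties broken by first type
in table order, logged). Categories: marker when AUC_max ≥ 0.8 —
anchored by the observation that canonical subclass markers all score
above 0.8 — intermediate (preferential/DE expression) when
0.6 ≤ AUC_max < 0.8, and ubiquitous when AUC_max < 0.6. The boundary
conventions (≥ at 0.8, strict < at 0.6) are part of the definition and
are tested on exact boundary inputs.

Marker counts per type use the same per-pair rule AUC(g, k) ≥ 0.8: a
gene above threshold in several types counts in each, but once in the
distinct total. The assignment curve reports, per AUC cutoff in
[0.5, 1], the mean ± SD number of types assigned per gene; genes with
zero assignments at a cutoff are excluded from the mean by default
(counting them as zero collapses the curve at high cutoffs; both modes
are available), and an alternative AUC_max-binned mode exists behind a
flag. Cell-type ordering for marker heatmaps uses average-linkage
hierarchical clustering of the types' AUC vectors under Euclidean
distance — a deterministic, seed-free choice.

## Gene-set statistics

Two samples of AUC_max values are compared with a two-sided
Mann–Whitney U test: exact enumeration when n_a·n_b ≤ 1000 and the
pooled sample is tie-free, otherwise the normal approximation with
tie-corrected variance and continuity correction (scipy's
implementation; the test suite checks it against an independent
exhaustive enumeration oracle). When every pooled value is identical
the tie-corrected variance is zero; p = 1 by convention. The median
difference (median_a − median_b) is reported alongside, and pairwise
grids carry raw-p significance stars (p < 0.05, p < 0.01) with optional
Benjamini–Hochberg q values — raw p is the default reporting mode.

The resampling null asks whether a gene set's AUC_max statistic
(median by default, mean optional) exceeds that of random same-size
gene sets: B draws without replacement from the detected-gene universe
(default B = 9,999), one-sided (greater) empirical p with add-one
correction p = (1 + #{null ≥ observed}) / (B + 1), so p is never 0 and
is super-uniform under the null (a tested calibration). Draws are not
matched on expression level; an exhaustive mode enumerates all subsets
for tiny universes. Subsets are derived from a single seeded generator
via a random-key/argpartition construction, so results depend only on
(seed, B, set size, universe order).

Genes of a set that are absent from the AUC table — undetected in the
dataset — are dropped before any comparison, with counts reported.
Constraint summaries report the median LOEUF of a set's matched genes
and the fraction strictly above the 0.6 constraint limit (LOEUF > 0.6 =
tolerant to loss of function). Cross-dataset consistency runs the same
two-sided Mann–Whitney per gene set between two datasets' AUC_max
samples; non-significance indicates replication.

## The simulator

The generator produces the minimal structure the rank-based statistic
responds to, not a facsimile of any real atlas. Per gene and type a
mean μ(g, k) is set by the planted role:

| role       | μ on target type(s)        | μ elsewhere | default            |
|------------|----------------------------|-------------|---------------------|
| marker     | marker_mean_in             | marker_mean_out | 10 vs 0.1       |
| de         | de_baseline_mean · de_fold | de_baseline_mean | 1 · 4 vs 1     |
| ubiquitous | ubiq_mean                  | ubiq_mean   | 2                   |

Counts are negative binomial with size (dispersion) r = 1 by default
(variance μ + μ²/r; `dispersion=None` gives the Poisson limit),
multiplied by a per-cell depth factor drawn log-uniformly from
[0.5, 2] — depth is the one nuisance AUC is not automatically invariant
to, and including it lets the `normalize_depth` flag be exercised.
Defaults are 4 types × 200 cells, 40 markers (round-robin, 10 per
type), 40 DE genes with 1–3 random target types each, and 100
ubiquitous genes; marker/DE/ubiquitous gene, cell and type names are
generated deterministically. Everything is a pure function of
(config, seed), bit-for-bit.

What the simulator does *not* model: batch effects, doublets, ambient
RNA, gene–gene correlation, cell-state continua, or realistic
mean–dispersion trends. Passing recovery tests therefore demonstrates
that the statistics behave as designed under their own assumptions —
clean labels and independent NB counts — not that any particular recall
would be achieved on real tissue atlases.

Companion generators build gene sets of controlled role composition
(so the expected direction of set comparisons is known) and a synthetic
LOEUF table: by default markers draw from Uniform(0.2, 1.1) — placing
roughly half their mass above the 0.6 limit, i.e. markers are the
*least* constrained role — DE genes from Uniform(0.1, 0.9) and
ubiquitous genes from Uniform(0.05, 0.7). These are synthetic stand-ins
chosen only to give `constraint_summary` a detectable, directionally
realistic contrast; they are not fit to any constraint release.

## Pipeline and reproducibility

The CLI stages (simulate → auc → classify → compare) are thin wrappers
over library functions. All randomness flows from one `--seed`;
rerunning any stage with identical inputs and seed reproduces every
output byte for byte (tested). Each stage writes a JSON manifest with
the effective parameters, package/library versions and SHA-256
checksums of its inputs. TSV floats use a fixed `%.12g` format; AUC
tables round-trip value-identically, carrying their level and per-type
cell counts in header comments.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` run at desk scale: default
simulations of 800 cells × 180 genes, 1,000 random instances for the
dual-route equivalence property, 2,000 repetitions at B = 499 for
resampling-null calibration, and 100 seeded simulations of 1,000 cells
for the null-gene AUC reference. These sizes give stable estimates for
every tested tolerance while keeping the whole suite in the order of
seconds.

## Known limitations

- One-vs-rest only; no multi-positive-class ROC, no DE p values or
  fold-changes.
- AUC on raw counts inherits any depth confounding present in the
  data unless `normalize_depth` is used; neither mode is a substitute
  for upstream QC, which the readers deliberately do not perform.
- The resampling null draws genes unmatched on expression; an
  expression-matched null would be stricter for sets with unusual
  detection profiles.
- Exact Mann–Whitney p values are only available for tie-free small
  samples; AUC_max samples from discrete counts frequently tie, in
  which case the tie-corrected normal approximation is used.
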
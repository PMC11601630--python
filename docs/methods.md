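# Methods

## The model

The package treats gene age as a phylostratum: the depth, in integer edges
from the root of a rooted species tree, of the most recent common ancestor
(MRCA) of the focal species and the most distantly related species sharing
an ortholog group with the gene. The tree is purely relational — branch
lengths in the input are discarded (with a one-time warning) and every edge
counts as 1 — so depths are comparable only within one tree. Lower depth
means an older gene; this root-anchored coordinate is kept primary
throughout rather than a reversed "rank" scale, so that "older" always
means "smaller number".

Age assignment is a pure minimum: for each focal gene, over every member
species of every group containing it, take the smallest MRCA depth. A gene
appearing in several groups takes the oldest evidence across all of them.
Species present in a group but absent from the tree are skipped and
counted, not fatal — real ortholog exports always contain stragglers.
Focal-only groups yield the focal leaf depth (the youngest class) rather
than an exclusion, because the youngest strata are biologically meaningful
and otherwise empty. Genes that cannot be aged are excluded with one of
three reason codes (`no-group`, `species-not-on-tree`,
`empty-after-filtering`); the reason taxonomy is this package's own.

Pleiotropy is measured two ways, deliberately not collapsed into one
score. The BP count is the number of distinct directly-annotated
biological-process terms — no ancestor propagation before counting, since
propagation would inflate every count with non-leaf ancestors; all evidence
codes are retained; duplicate annotations of one process count once. The
PPI count is the node degree over edges whose confidence strictly exceeds
0.66 ("surpassed" read as `>`; an inclusive `>=` mode exists, and the
synthetic generator keeps confidences away from the boundary so both modes
agree). Genes absent from the network are *missing*, not zero, and are
dropped from PPI analyses only.

Broad functional categories are the direct `is_a` children of the BP root
(GO:0008150), reached by ancestor traversal over `is_a` edges only —
`part_of` and other relations are ignored, matching the minimal OBO subset
the readers accept. The per-gene *primary* category, used as the factor in
the two-way ANOVA, is the membership category covering the largest number
of the gene's annotated terms, with lexicographic term-id tie-break; the
underlying multi-membership sets are also kept, since a gene-by-category
long format is the natural alternative and neither convention is forced on
the user.

Duplication status is binary: at least one paralog means duplicated.
Absence from the paralog table means *missing data*, never "zero
paralogs"; duplication analyses silently narrow to genes with data and the
exclusion is logged.

## Statistics

Age enters every ANOVA as a single continuous covariate (1 df), not as a
binned factor: ages live on an ordered integer scale and a single-df trend
test is both the more powerful and the more parsimonious choice for a
monotone hypothesis. The two-way analyses use a sequential (type-I)
decomposition fitting age first, then the categorical factor, main effects
only; sums of squares come from the drop in residual SS across nested
ordinary-least-squares fits. F statistics use the residual mean square of
the full main-effects fit. Perfect fits (residual SS at rounding-noise
level, below 1e-12 of the total) and constant responses are flagged rather
than reported as spuriously infinite or undefined without comment.

Group means are compared by percentile bootstrap: with m the smallest
group's size, each of B = 10,000 resamples (default) draws m observations
with replacement from a group, and the 95% CI is the 2.5–97.5 percentile
interval of the resample means. Resampling every group at the common m
removes sample-size artefacts from the comparison. A pairwise
CI-disjointness table is reported; disjointness is a conservative
indication of separation, not a formal test. B, the percentile method and
the single RNG seed are all explicit in the output.

Bin summaries report `log10` of the scores for plotting, excluding zero
and missing values (log of zero is undefined; missing means no data), while
all ANOVAs run on the raw counts — the transform belongs to the
visualisation, not the test.

ANOVAs on counts rely on the usual large-sample robustness of the F test
under i.i.d. non-normal errors; the calibration study below checks that
this is adequate at the sizes used. Genes are treated as independent
observations — no phylogenetic or network autocorrelation is modelled.

## Synthetic data: what it emulates and what it does not

The generator plants a known structure: each gene receives an age (uniform
over the achievable MRCA depths by default), one or two of 16 broad
categories, a duplication flag (probability 0.3), and a BP count

    bp = 1 + Poisson( exp(b0 + b1 (D − a) + Σ category effects + b_dup · dup) )

with D the focal leaf depth. Defaults: a 12-species caterpillar tree
(D = 11, every depth 0–11 achievable), 2000 genes, b0 = 0.5, b1 = 0.25,
metabolic −0.3 and developmental +0.3 on the log mean, b_dup = 0.3. These
sizes give oldest-stratum mean BP counts of a few tens — the scale real
genomes show — while the +1 shift reproduces the observed single-process
floor. The PPI degree follows the same log-linear form (intercept 0.8,
slope 0.15) without the shift.

The ortholog group of a gene with age a contains the focal species, a
partner species whose MRCA depth is exactly a (omitted when a = D,
producing a species-specific gene) and a few extra members at
equal-or-greater depth, never shallower — so the planted minimum is exact
and age recovery must be 100%, for every seed and tree shape. Annotations
are bp distinct leaf terms drawn from the gene's categories (a config error
if a category's leaf pool is too small); the truth table records the
categories actually represented among the drawn terms, since a
two-category gene can draw all its terms from one pool. The intended PPI
degree sequence is realized by stub matching, which can drop a stub (odd
stub total, repeated pair); the truth records the *realized*
above-threshold degree, keeping truth and emitted files consistent by
construction. Passing confidences are sampled from (0.672, 1.0) and failing
noise edges from (0, 0.65), so the 0.66 threshold decision is unambiguous
under either comparison even after rounding to the 0–1000 integer scale.

One master seed streams to per-component child seeds (tree, gene table,
annotations, PPI, groups), making outputs byte-identical per seed while
components stay independently regenerable.

What the generator does **not** emulate: sequence evolution, gene
birth–death along the tree, correlated annotation error, GO term depth
heterogeneity, hub structure in the PPI network, or any dependence between
genes. Passing tests therefore demonstrate that the pipeline computes its
quantities correctly and that the statistics are calibrated under the
assumed independent log-linear structure — not that real ortholog or GO
data satisfy those assumptions.

## Numerical and design choices

- Binning closes a bin at count ≥ threshold (a strict `>` mode exists);
  the trailing under-threshold youngest bin is kept and flagged so
  downstream analyses can drop it knowingly.
- Duplicate PPI edges keep the maximum confidence — conservative for a
  threshold rule. Self-loops are dropped.
- Score-scale detection: any score above 1 implies the 0–1000 integer
  scale and all scores are divided by 1000; re-reading a written 0–1 file
  is a no-op.
- Rank-deficient two-way designs raise an error naming an aliased factor
  level rather than silently dropping a column.
- The panel filter drops a selected category below `min_genes = 50` —
  a deliberate explicit floor for "too few genes for effective comparison".
- All output tables are plain TSV with deterministic row order; the run
  manifest (JSON) echoes config, seed, version and per-stage counts.

## Problem sizes in the test and acceptance studies

The calibration studies use an 8-species tree (focal depth 7): with the
planted slope 0.5 this keeps the oldest-stratum mean BP near exp(4) ≈ 55,
a plausible ceiling, and the per-category leaf pools comfortably larger
than any drawn count. Type-I error is estimated from 1000 null datasets of
500 genes; power and bin ordering from 200 datasets of 2000 genes;
bootstrap coverage from 500 Poisson simulations of two groups of 100 at
B = 1000; oracle equivalence from 100 random trees (≤ 64 leaves, with
polytomies, one instance at 10,000 genes) and 1000 random binning
profiles.

## Known limitations

- Ages are tree-relative integers; comparing ages across different trees
  or species sets is meaningless.
- The shared gene-id namespace across ortholog, annotation, PPI and
  paralog files is assumed, not checked against external id maps.
- OBO support is a minimal subset (`is_a` only); ontologies relying on
  `part_of` for BP placement will under-assign categories.
- No multiple-testing correction across species or scores is applied;
  p-values are reported raw.
- The bootstrap CI is the simple percentile interval; it inherits that
  method's slight undercoverage at small m.
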
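# pleiostrat

Comparative-genomics pipeline relating **gene age** to **genetic pleiotropy**.
It assigns each gene of a focal species a phylostratigraphic age from
ortholog groups on a rooted species tree, quantifies the gene's pleiotropy
two complementary ways — unique GO biological-process (BP) count and
high-confidence protein–protein-interaction (PPI) degree — and runs the
comparative statistics across age bins, broad functional categories and
gene-duplication status. A synthetic-data generator with planted effects
makes the whole chain testable without any database download.

Intended users: evolutionary genomicists studying how gene function
accumulates over evolutionary time, and anyone who needs a tested
implementation of MRCA-depth gene aging, adaptive age binning, or
thresholded-degree pleiotropy scoring on their own ortholog/GO/PPI exports.

## Method

**Gene age.** The species tree is purely relational: every branch counts as
length 1, so each node has an integer depth (edges from the root). For the
focal species *f* and any species *s*, let `d(s) = depth(MRCA(s, f))`. A
gene's age is

```
age(g) = min { d(s) : species s shares an ortholog group with g }
```

taken over *all* groups containing the gene — the oldest shared ancestor
wins, so **lower depth = older gene**. A gene found only in the focal
species gets the focal leaf's own depth, the youngest assignable age. Genes
that cannot be aged are excluded with a reason code (`no-group`,
`species-not-on-tree`, `empty-after-filtering`).

**Age bins.** Raw ages are collapsed oldest-first into ordered bins each
holding ≥ 1000 genes (configurable); the trailing youngest bin may be
under-threshold and is kept flagged.

**Pleiotropy.** `bp_count` = number of *distinct* BP terms annotated to the
gene (all evidence codes kept, duplicates ignored, non-BP namespaces not
counted). `ppi_count` = number of incident PPI edges whose confidence
surpasses 0.66 (strictly greater; STRING-style 0–1000 scores are detected
and divided by 1000). Genes absent from the network are *missing*, not zero.

**Broad categories.** The direct children of the BP root `GO:0008150`
(metabolic process, developmental process, …). A gene belongs to a category
when any of its annotated terms reaches it through `is_a` ancestors; its
*primary* category is the one covering most of its terms (lexicographic
tie-break).

**Statistics.** One-way ANOVA of a score on continuous age (df = 1);
sequential (type-I) two-way ANOVA adding the category or duplication factor
after age, main effects only; percentile-bootstrap group means with 95% CIs
resampled at the smallest group's size; per-bin `log10` summaries for
plotting (ANOVAs always run on raw counts).

## Worked example

Generate a synthetic bundle with a planted positive age effect and run the
full pipeline:

```bash
pleiostrat simulate --out sim --seed 4 --n-genes 2000
pleiostrat run-all --tree sim/tree.nwk --orthologs sim/orthologs.tsv \
    --obo sim/go.obo --annotations sim/annotations.tsv --ppi sim/ppi.tsv \
    --paralogs sim/paralogs.tsv --focal S00 --out results \
    --bin-threshold 200 --seed 4
# 2000 genes aged (100% retained), 6 bins, tables in results
```

`results/anova_bp_age.tsv` then holds the one-way ANOVA of BP count on age:

```
Factor  df    sum_sq     mean_sq      F        PR(>F)
Age     1     120882.26  120882.26    4732.42  0.0
Residual 1998 51035.74   25.54
```

— the planted age effect is detected (F ≈ 4732 on 1 and 1998 df). The
generator's default slope makes old genes more pleiotropic, and the bin
summaries show it: the oldest bin (depths 0–1) has mean BP ≈ 27.4 versus
≈ 3.1 in the youngest (depths 10–11). `results/bootstrap_ci.tsv` gives the
bootstrapped category means (resample size = smallest group, here 117):

```
group                  mean   ci_low  ci_high
cellular process       11.22   9.60   12.93
developmental process  13.86  11.87   15.98
immune system process  10.48   8.93   12.09
metabolic process       8.04   6.95    9.17
```

Metabolic genes are the least pleiotropic and developmental the most —
exactly the planted category effects (−0.3 and +0.3 on the log mean).
`results/gene_features.tsv` holds the per-gene table (age, bin, BP count,
PPI count, categories, duplication flag) and `manifest.json` the run echo.

The same stages are available as library functions
(`pleiostrat.assign_ages`, `bin_ages`, `bp_count`, `ppi_count`,
`anova_one_way`, …) and as individual CLI subcommands
(`age`, `bin`, `score`, `classify`, `duplication`, `report`).

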
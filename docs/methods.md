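# Methods

## Scope and data model

`stagetraffic` starts from a cell × gene UMI count matrix whose cells
carry one of four germline cell-type labels — spermatogonia, early
spermatocytes, late spermatocytes, spermatids — plus a gene annotation
table (chromosome arm ∈ {2L, 2R, 3L, 3R, 4, X, Y}) and a parental/new
gene table (child, parent or blank for de novo, age branch 1–6, mechanism
DNA / RNA / DENOVO). Upstream single-cell processing (alignment, doublet
removal, integration, clustering, marker-based annotation) is out of
scope: labels arrive as input. Somatic cell types are likewise out of
scope; the analysis concerns the germline.

## QC and pseudobulk aggregation

Genes detected (count > 0) in at least 3 cells and cells with at least
200 detected genes are kept. Both masks are computed on the input matrix
and applied jointly in a single pass; an `iterative` flag re-applies the
two filters to a fixed point for users who prefer a self-consistent
matrix. "Expressed" always means UMI ≥ 1; no threshold parameter is
exposed because none is defensible at UMI depths.

Per cell, CPM = count × 10⁶ / cell total, computed over the post-QC gene
set. Per gene and cell type the profile records the mean of log₂(CPM + 1)
across that type's cells and the percentage of those cells with a nonzero
count. Aggregation is invariant to cell order and to rescaling any cell's
depth by a constant. Multiple matrices can be concatenated after per-cell
CPM; no batch correction is applied and a warning says so.

## Stage classification

Silent genes (all four means zero) are set aside as `not_expressed`.
Remaining rows are z-scored (sample SD, ddof = 1; constant rows map to
zeros), then clustered by complete-linkage agglomerative clustering on
Euclidean distance and the dendrogram is cut into k = 7 clusters. Genes
are processed in sorted gene-id order, making the result independent of
input row order. Euclidean distance is the conventional choice for
row-scaled expression heatmaps; both k and the distance input (mean
profile vs percent-expressing profile) are exposed.

Each cluster is mapped to a category through its centroid's **enriched
set**: the cell types whose centroid value exceeds both an absolute
threshold θ (default 0) and `rel_enrich` = 0.5 × the centroid's peak
value. The relative criterion exists because a z-scored 4-vector with one
dominant cell type routinely leaves a second cell type sitting at z ≈ 0:
whether it lands at +0.01 or −0.01 is sampling noise, and an absolute cut
at 0 would flip entire clusters between adjacent categories. Requiring
half the peak makes "enriched in both" mean both cell types genuinely
share the program. The mapping is

| enriched set | category | rank |
|---|---|---|
| {SPG} | mitosis | 1 |
| {SPG, early} | mitosis_meiosis | 2 |
| {early}, {late}, {early, late} | meiosis | 3 |
| {late, SPT} | meiosis_postmeiosis | 4 |
| {SPT} | postmeiosis | 4 |

Non-contiguous or 3+-type sets fall back to the contiguous candidate with
the largest mean centroid value (ties broken in stage order); an empty
set falls back to the argmax cell type; both fallbacks are logged.
Postmeiotic genes are few, so postmeiosis shares rank 4 with
meiosis_postmeiosis and the two are pooled in enrichment tests.

The percent-expressing variant runs the identical pipeline on the
pct rows. Note its information content depends on dropout: at very high
sequencing depth every weakly expressed gene is detected in every cell,
the pct rows saturate near 100 and the variant degrades. It agrees with
the mean-based classification exactly in the noiseless shallow-depth
regime and is intended as a robustness check, not a replacement.

## Chromosomal enrichment

Counts are tabulated densely over chromosome × category. Each of the dot
(4), X and Y chromosomes is tested against the pooled major autosomes
{2L, 2R, 3L, 3R} with a two-sided Fisher exact test per category on
[[n_cat,C, n_other,C], [n_cat,A, n_other,A]], excluding `not_expressed`
genes from the margins (an expressed-vs-not test is available separately,
relevant for the gene-poor Y). Meiosis and postmeiosis are pooled by
default ("meiosis+postmeiosis"), with an `all_meiotic` mode that also
pools meiosis_postmeiosis. Raw p-values drive the significance flags, as
is conventional for these single-table comparisons; Benjamini–Hochberg
q-values over each stratum's family of category tests are reported
alongside. The normalized ratio per stage is
(n_cat,C / n_C) / (n_cat,A / n_A); zero denominators yield NaN with a log
entry.

## Pair stage shifts

Stage ranks 1–4 run from spermatogonia to spermatids. A pair's shift is
child rank − parent rank (−3…+3). Direction classes partition the 16 rank
pairs by whether they cross the mitotic {1,2} / meiotic {3,4} boundary:
into_meiosis (mitotic parent, meiotic child), into_mitosis (the reverse),
within_mitotic, within_meiotic. Crossing the boundary takes precedence
over the size of the step, which makes the taxonomy a true partition; a
(1 → 4) pair is an into-the-meiosis change of +3. Pairs with an
unexpressed member are recorded as unclassified and excluded from shift
statistics but retained for composition plots.

Routes are derived from the annotation: X→A means an X-linked parent and
a child on a major autosome; movements touching the dot or Y chromosome
are "other". Non-overlap percentages map each category to its cell-type
set ({SPG}, {SPG, early}, {early, late}, {late, SPT}, {SPT}) and count a
pair when the sets are disjoint. Composition comparisons are per-category
two-sided Fisher tests between two gene sets (children vs parents per
stratum; de novo children vs all annotated genes as the genomic
background, since they have no parent).

## Gene traffic

Under the null, movement from source i to target j is proportional to
the parental gene count of i and the physical length of j:
E[i→j] = N (g_i/Σg)(L_j/ΣL). Retroposition is treated as
inter-chromosomal: the diagonal is zeroed and each row renormalized to
preserve its total. The out-of-the-X test collapses cells into classes —
default X→A versus all other inter-chromosomal movements — and computes
the plain Pearson chi-square Σ(O−E)²/E with df = classes − 1. A Yates
continuity correction is available but off by default. A hook accepts an
empirical target-frequency vector in place of length-proportional
insertion. Collapsed expected counts below 1 trigger a warning. Default
chromosome lengths are the reference arm lengths of the *D. melanogaster*
assembly; supply a TSV to override.

## Synthetic data generator

Genes follow one of five archetype programs over the four cell types
(relative means; only the rank structure matters downstream):

```
mitosis              (1,    0.1,  0.05, 0.05)
mitosis_meiosis      (1,    1,    0.1,  0.05)
meiosis              (0.05, 1,    1,    0.1 )
meiosis_postmeiosis  (0.05, 0.1,  1,    1   )
postmeiosis          (0.05, 0.05, 0.1,  1   )
not_expressed        (0,    0,    0,    0   )
```

Within each cell type, per-gene means are the program values normalized
over genes and scaled to the mean library size (default 5000 UMI/cell, a
typical droplet depth). Counts are negative binomial with dispersion α
(variance μ + αμ²; α = 0 gives Poisson; default α = 0.3, moderate
overdispersion). Chromosomes are drawn from a probability vector
defaulting to the approximate arm shares of the genome. Defaults: 100
genes per archetype and 100 cells per cell type.

Pairs are planted per (route, mechanism) stratum, 100 pairs each for the
six inter-chromosomal strata plus intra-chromosomal DNA pairs and de novo
genes. Parents are drawn from source-chromosome genes with
mitosis-weighted archetype probabilities (0.5 / 0.2 / 0.2 / 0.05 / 0.05),
reflecting that progenitors of testis new genes are predominantly
mitotic. With probability `p_into_meiosis` — default 0.3 everywhere,
raised to 0.6 for (X→A, RNA), the planted MSCI-driven signal; both values
are configuration, not hard-coded — the child's archetype is drawn
uniformly among ranks strictly above the parent's (parents are restricted
to ranks 1–3 when a shift is planted); otherwise the child inherits the
parent's archetype, so with no planted bias the shift distribution is
centered at zero. Children are new genes appended to the annotation on
the route's target chromosome; retrogenes get a single exon. Everything
is driven by one master seed; identical seed and configuration reproduce
byte-identical outputs.

What the generator does **not** emulate: read- or UMI-level artifacts,
doublets, ambient RNA, batch effects between strains, continuous
developmental trajectories within a cell type, or correlated gene
programs. Passing recovery tests therefore demonstrates that the pipeline
is correct and well-conditioned under a clean overdispersed-count model,
not that the stage categories of real testis data are free of annotation
or integration artifacts.

## Problem sizes and numerical choices

Recovery tests use the default 600-gene universe; the replicate-level
detection of the planted X→A retroposition bias uses 50 seeded replicates
of pair planting (100 pairs per stratum) evaluated on the planted
archetypes, which isolates the detection question from count noise.
Noise-robustness is checked at dispersions 0, 4 and 40 without the QC
step, since at extreme dispersion dropout starves cells below the
200-gene threshold and would measure QC attrition rather than
classification error. Fisher tests use the exact conditional null;
chi-square p-values come from the upper tail of the χ² distribution.
Cluster ids are relabeled in order of first appearance after canonical
gene sorting, making runs deterministic across platforms. Degenerate
inputs (zero margins, empty strata, all-silent genes, single-gene
clusters) return flagged neutral values or explicit errors, never silent
drops.

## Known limitations

- The 7-cluster cut and the enriched-set mapping are an operationalization
  of "divide clusters by expression pattern"; other defensible mappings
  exist, and θ / `rel_enrich` / k are exposed for that reason.
- CPM + log pseudobulk averaging is simple and transparent but not a
  variance-stabilizing transform; rank structure, which is all the
  classifier uses, is robust to this.
- The traffic null attributes target choice to physical length only;
  insertion-site biases are absorbed by the empirical target-frequency
  hook, not modeled.
- With only four cell types, stage resolution within spermatocytes is
  coarse; "early" vs "late" spermatocyte distinctions carry all meiotic
  sub-structure.
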
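# Methods

This note documents the models, defaults, and numerical choices behind
cfmeth, and what the synthetic-data tests do and do not demonstrate.

## Input model

The pipeline consumes per-CpG methylation calls in the methylation-extractor
bedGraph dialect (chrom, start, end, percent, methylated count,
unmethylated count). Counts are authoritative; the percent column is never
trusted, so β = n_meth / n_total is always a ratio of the stored integers.
Coordinates are 0-based half-open; a call row (start, start+1) maps to the
cytosine position `start`. Calls are assumed already destranded (symmetric
CpG calls merged upstream by the extractor); cfmeth does not re-collapse
strands. Zero-coverage CpGs are legal input and flow through the coverage
filter rather than being silently dropped.

## Region calling

Segmentation is 1-D mean shift with a flat (top-hat) kernel over CpG
coordinates. For each site, x ← mean of all sites in
[x − w/2, x + w/2] until the shift is below `shift_tol_bp` or `max_iter`
is reached. Methylation values do not weight the shift: the density being
climbed is positional CpG density, and methylation enters only through the
pooled counts of the resulting regions. The CpG universe is the union of
covered positions across all samples — one region catalogue for the whole
cohort — and a CpG absent from a sample contributes (0, 0) to its pooled
counts.

Parameters (units bp unless noted):

| parameter | default | role |
|---|---|---|
| `bandwidth_bp` | 200 | full window width; matches the CpG-island length scale |
| `shift_tol_bp` | 0.5 | sub-bp convergence |
| `max_iter` | 100 | iteration cap |
| `merge_dist_bp` | 200 | single-linkage merge distance on converged modes |
| `min_cpg` | 3 | minimum CpGs per reported region |

`merge_dist_bp` defaults to one full window rather than half of one. With
a flat centred window the converged modes of a single dense ~250 bp island
can legitimately sit up to ~150 bp apart (mode plateaus on either side of
an internal density dip), so merging at w/2 fragments a meaningful share of
islands, while genomically distinct islands are separated by kilobases and
can never merge at w. Measured on planted layouts this choice recovers
> 99 % of islands as exactly one region.

Ties cannot arise in the centred-window update (the mean is unique), and
plateaus resolve deterministically to the window mean. Translating all
positions translates all modes, and re-running the iteration from returned
modes moves nothing beyond tolerance; both properties are tested.

## DMR testing

The 2×2 Fisher table pools reads across samples within each group. With
3 vs 4 samples a per-sample test has essentially no power; pooling ~10 CpGs
at ~25× per sample yields count scales at which p < 10⁻⁸ is reachable,
which is the regime the default thresholds (p < 1e-8, |Δ| ≥ 0.10) assume.
The two-sided p is the sum of hypergeometric point probabilities not
exceeding the observed table's probability, with a 1 + 1e-7 relative
inclusion tolerance on the comparison; any zero margin gives p = 1. The
implementation is validated against exact integer enumeration on every
table with all margins ≤ 30 and against an independent library
implementation on random tables.

Δ is the difference of group means of per-sample pooled ratios (not a
ratio of pooled counts), so each sample carries equal weight regardless of
depth; samples with zero pooled coverage in a region are excluded from
their group's mean, and the region is skipped if a group has no covered
sample. Direction is "hyper" when the case group is more methylated.

The coverage rule keeps a CpG when its read total summed over the whole
cohort reaches `coverage_multiplier × n` (default 2n with n the cohort
size); a `per_group` scope that applies 2 × group-size within each group is
available as a configuration switch. Raw p is the calling criterion; a
BH-adjusted q over all tested regions is attached for information only.

Annotation: promoter = 5000 bp upstream of the TSS (strand-aware), gene
body = the TSS–TES span, otherwise intergenic. Promoter takes precedence
on double overlap, and among multiple candidate genes the nearest TSS (by
absolute signed midpoint distance, ties by gene id) wins, so the reported
categories partition the calls. The gene-overlap significance test is an
upper-tail hypergeometric — the one-sided Fisher equivalent.

## Signature selection

The region × sample β matrix uses pooled per-sample region β; entries
below `min_coverage` pooled reads are masked and rows with masked entries
dropped by default (mean imputation optional). PCA is the thin SVD of the
column-centred samples × regions matrix, so at most n − 1 components carry
variance; β already lives on a common [0, 1] scale, so rows are not
variance-scaled. The group-informative component minimises the two-sided
Welch-t p of its sample scores between groups (ties to the lower index;
numerically null components are excluded). Selection keeps the top
⌈fraction · n_regions⌉ regions by absolute loading — loading signs are
arbitrary under SVD, and all downstream results are invariant to sign
flips (tested); magnitude ties break by genomic order. Selected regions
map to genes through the same promoter/body rules as DMR annotation.

## EMT-Met score

For a sample's gene-level β vector and reference sets E and M, the score
is AUC of the M-gene ECDF minus AUC of the E-gene ECDF, both integrated
over the fixed domain [0, 1] (not the observed range — this is what makes
the bounds ±1 exact and gives the closed form score = mean β_E − mean β_M,
which serves as the module's primary test oracle). Gene-level β is the
unweighted mean over a gene's associated regions; a CpG-count-weighted
mean is available. Per-sample normalization before scoring is configurable
(`rank_uniform` default, mapping the i-th smallest of n values to
(i − 0.5)/n with average ranks on ties; `minmax`; `none` reproduces raw-β
scoring). Phenotype is mesenchymal iff score > 0.

Group comparison uses a two-sided Welch t-test by default (Mann–Whitney
optional; with 3 vs 4 samples an exact rank test cannot reach small
p-values, so a t-test is the only usable default at this design size).
ROC AUC uses the rank (Mann–Whitney) formulation with half-credit for
ties and is checked exhaustively against pair counting. Stage summaries
report the fraction of samples with score > 0 per stage.
Methylation–expression association is a Pearson correlation with the
two-sided t-transform p.

## Over-representation

Hypergeometric upper-tail tests per gene set, BH step-up FDR across the
sets tested. The default universe is the set of genes carrying at least
one measured region, not the whole annotation — testing genes that could
never have been called only dilutes the null. Sets with fewer than 3
members inside the universe are skipped (with a warning) rather than
tested meaninglessly.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 4 control
vs 3 case samples, mean per-CpG depth 25× (Poisson), CpG islands of mean
length 250 bp with ~10 CpGs, islands ≥ 2 kb apart on one synthetic
chromosome, sparse background CpGs (0.5/kb, β ≈ 0.75) between them.
A planted fraction of islands (default 0.2) are DMRs: the case-group mean
β shifts by ±0.3 (random sign) from a baseline drawn uniform in
[0.35, 0.65]. Disjoint from these, islands in the promoter windows of
planted epithelial genes move 0.30 → 0.50 in the case group and
mesenchymal-gene islands 0.60 → 0.30 — promoter hypermethylation of
epithelial genes and hypomethylation of mesenchymal genes, the methylation
signature of an epithelial–mesenchymal transition — so case samples score
mesenchymal. E/M islands are separate from DMR islands so signature
recovery and DMR recovery are independently testable.

Island geometry is deliberately "island-like": the terminal CpGs sit at
the span edges (so the region hull matches the configured length
distribution), the CpG count tracks the span at constant density
(Poisson with mean span/25), and intra-island CpG spacing is capped at
80 bp by redrawing the uniform positions. Real CpG islands are dense,
quasi-regular CpG runs; spacings larger than half the segmentation window
would make the layout unresolvable by any fixed-window density method and
do not correspond to island biology.

Replicate noise is beta-binomial: each island draws one β per sample from
a Beta centred on the group mean with concentration 200, then binomial
counts at the Poisson coverage. The concentration is a stand-in — no
published estimate of inter-individual cfDNA β dispersion at region scale
was available — and was fixed by a design calculation, not fitted: at
concentration c the per-sample region β has sd ≈ √(0.25/(c+1)); the pooled
Fisher test at p < 1e-8 over ~10 CpGs × 25× × 3v4 samples triggers at
|Δ̂| ≈ 0.14, so c = 200 (β sd ≈ 0.035 per sample) puts the null call rate
near 10⁻⁴ per region — real replicate-level overdispersion with a caller
that stays essentially silent on nulls, the regime a p < 1e-8 threshold
implies. Much smaller concentrations make the pooled Fisher test
anti-conservative far beyond anything the published thresholds could have
tolerated.

Determinism: the layout derives from `seed` alone and samples from a
spawned seed sequence, so identical configs give byte-identical files.

**What passing tests show — and do not.** The generator realises the
stated design (effect sizes, depth, geometry) with idealised noise:
independent islands, a single chromosome, symmetric beta-binomial
replicates, no fragment-length or bisulfite-conversion artefacts, no
copy-number or tumor-purity variation, and gene models built to pair
cleanly with islands. Recovery results therefore validate the inference
machinery under its own assumptions; they do not certify performance on
real cfBS data, where dispersion is heavier-tailed and regions are not
independent.

## Problem sizes in the test suite

The default simulated cohort used by the recovery tests has 1200 islands
(~13,500 CpGs × 7 samples), large enough to measure a false-call rate on
a per-1000-null-regions scale; segmentation fidelity uses 500 islands;
signature recovery uses 200 replicates of a 1000-region × 7-sample matrix;
Fisher exactness enumerates all ~164,000 tables with margins ≤ 30. These
sizes keep the full suite around half a minute while leaving every
assertion statistically meaningful.

## Known limitations

* Mean shift is exact but O(n · iterations) per chromosome with a fixed
  window; no adaptive bandwidth is attempted (the source method's
  "initial size" hints at adaptation, but no update rule is defined, so
  the window stays fixed).
* The pooled Fisher table treats reads within a group as exchangeable;
  replicate overdispersion beyond the simulated regime will make raw
  p-values anti-conservative on real data. The |Δ| filter is the main
  guard.
* `pick_informative_pc` tests each component marginally; correlated or
  split group signals across components are not pooled.
* The EMT score ignores gene-level coverage weights by default; genes
  measured by one noisy region count as much as well-covered ones.
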
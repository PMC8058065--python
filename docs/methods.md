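# Methods

This note documents the models, procedures and numerical choices behind the
`enhancerome` package: a pipeline for characterising the tumor enhancer
landscape from chromatin-state segmentations, testing transcription-factor
enrichment against a constrained genomic shuffle, clustering pan-cancer
accessibility, and scoring single cells with a regulatory gene signature.

## Coordinate conventions and the interval engine

All genomic coordinates are 0-based, half-open (BED convention); readers
for 1-based formats would convert at the boundary. Interval sets are kept
sorted by (chromosome, start, end). Merging joins overlapping intervals
and, by default, book-ended ones (`[a,b)` + `[b,c)` → `[a,c)`), matching
the usual semantics for building master peak lists. Strand is ignored
throughout: every operation in the pipeline is strand-agnostic.

Peak summits come from the narrowPeak summit column when present
(column 10; −1 means absent) and otherwise fall back to the floor midpoint
`⌊(start+end)/2⌋` — a deterministic, strand-free convention.

### Constrained shuffle

The permutation null repositions a set of features inside a background
region set minus an excluded set. The multiset of feature lengths is
preserved exactly. Placement is uniform over valid start positions: an
eligible background interval of width `w` can host a feature of length `L`
at `w − L + 1` starts, so the interval is chosen with probability
proportional to that count and the start uniformly within it. Shuffled
features may overlap one another — the behaviour of standard
genome-shuffling tools; a non-overlapping mode is deliberately out of
scope. A feature longer than every eligible background interval is an
error naming the feature.

Inside the permutation test all `n_perm` draws come from a single seeded
`numpy` Generator in one vectorised pass (features grouped by length); a
fixed seed reproduces the null vector bit-for-bit.

## Enhancer catalogue

Each sample's genome is partitioned into eight chromatin states (active /
flanking TSS, active / flanking / weak enhancer, elongation, repressed,
quiescent). Active distal enhancers per sample are the merged
ActEnh ∪ FlnkActEnh segments, dropping merged regions

* shorter than 200 bp, and
* overlapping (≥ 1 bp) the ±5 kb window around any annotated TSS.

The any-overlap reading of the TSS window is the strictest one and
prevents promoter-proximal regions from leaking into the distal
enhancerome; the window and the minimum overlap are configurable.

Two master lists are maintained: the **consensus enhancerome**
(union-merge across samples, keeping regions supported by ≥ 2 samples at
≥ 1 bp overlap) feeds the differential analysis; the **conservation master
list** (≥ 1 sample) feeds the binary region × sample presence matrix.
Conservation tiers restrict master regions to those overlapping a gained
region and require a carrier frequency of at least `⌈t · n_samples⌉` for
tier `t` (0.5 and 0.8 by default), which makes tiers nested by
construction.

## Differential H3K27ac analysis

Counts over consensus regions are normalised with median-of-ratios size
factors (per-region geometric-mean reference computed on regions with
all-positive counts; factors rescaled to geometric mean 1). Each region is
then tested between tumor and normal groups with a two-sided Welch t-test
on `log2(normalised count + 1)`, BH-adjusted across regions. A region is
*gained* at `padj ≤ 0.01` and `log2FC ≥ 2` with
`log2FC = log2((mean_tumor + 1)/(mean_normal + 1))`; *lost* with the sign
flipped. The pseudo-count of 1 bounds fold changes when one group has zero
signal.

This is a deliberately transparent substitute for a negative-binomial Wald
framework: the scientific surface here is planted-effect recovery at the
stated thresholds, not the internals of any particular count model, and a
Welch test on log counts is well calibrated at these group sizes (the
suite checks a ~5% raw-p rate under the null). Dispersion shrinkage,
covariates and paired designs are out of scope.

## Conditional state-accessibility statistic

For accessibility peaks reduced to 1-bp summits and a genome partitioned
into states, the probability of open chromatin given state `i` is

    p(A | B_i) = (number of summits inside state i) / (length of state i)

with `p(A)` = summits / genome length, `p(B_i)` = state length / genome
length, and `p(A ∩ B_i)` = summits in state / genome length, so
`p(A|B_i) · p(B_i) = p(A ∩ B_i)` holds exactly (integer numerators over a
common denominator). Because peaks are reduced to summits the result is
invariant to peak widths, and a peak spanning several states is assigned
to the unique state containing its summit — the same rule is reused for
peak-distribution summaries so the two views cannot disagree.

## TF-enrichment permutation test

The statistic is the percentage of subset regions overlapping ≥ 1 TF peak
(a region overlapped by several peaks counts once). The null re-places the
subset's features within the enhancerome minus all gained regions, 1000
times by default, and the one-sided empirical p is the plain
`#{null ≥ observed} / n_perm` — ties count as extreme, and p = 0 is a
legitimate value meaning no shuffle reached the observed percentage. A
`pseudocount` option provides the conservative `(k+1)/(n+1)` variant,
off by default.

## Enhancer → gene annotation and enrichment

Enhancers overlapping an interaction anchor (capture-Hi-C-style pairs)
inherit that anchor's gene(s); all linked genes are kept and deduplicated.
Remaining enhancers go to the nearest *active* promoter: eligible genes
are protein-coding genes whose TSS lies inside the merged
ActTSS ∪ FlnkActTSS regions pooled across samples, distance is
|enhancer midpoint − TSS|, and exact ties break to the lexicographically
smallest gene identifier. An enhancer with no eligible gene on its
chromosome is reported unannotated rather than erroring.

Gene lists are tested per gene set with a one-sided hypergeometric
(Fisher) test after intersecting each set with the universe; BH adjustment
across sets; significance is adjusted p < 0.05 (strict).

## Pan-cancer accessibility

Each enhancer is matched to the best overlapping accessibility peak
(highest score; ties to the leftmost start). The enhancer × sample matrix
of log2-normalised scores is collapsed to per-type means — so types with
more samples do not dominate distances — and rows are clustered by
agglomerative hierarchical clustering (Euclidean distance, complete
linkage) with a 2-cluster cut. Within the cluster of higher grand mean,
"accessible in all cancer types" is operationalised as exceeding the
median pooled over the whole matrix in *every* type. A single pooled
threshold is used because in the colon-like type every panel enhancer is
accessible, so a per-type median would sit among the high values there and
discard genuine pan-accessible rows. Both the number of clusters and the
membership quantile are parameters. If no row passes the membership test
(e.g. a constant matrix) the result is an empty set with a warning, not an
error.

## Single-cell signature scores

For a cell `C` and gene set `G`:

* `c_score` — fraction of `G`'s genes with expression > 0 in `C`;
* `e_score` — `Σ_{g∈G} C_g / Σ C`, the set's share of total expression;
* `combined = c_score · e_score`;
* `final = 1 / (−log combined)`.

The logarithm is natural by default (configurable base); `combined = 0`
maps to `final = 0`, and the singularity at `combined → 1` is capped at
`1/(−log(1 − ε))` with `ε = 10⁻⁶`. The transform is strictly increasing
on the interior, and all four quantities are exactly invariant to
rescaling a cell's expression vector — so they can be computed on raw or
normalised matrices alike, with "expressed" meaning > 0 on whichever
matrix is supplied. Cells with zero total expression are an error for
`e_score`; callers drop them beforehand. Population comparisons use the
two-sided Wilcoxon rank-sum test on final scores.

## Synthetic cohort

The generator builds a toy study whose statistical structure mirrors a
tumor-organoid cohort: 10 tumor and 5 normal segmentations over a 4 Mb
genome (10 chromosomes of 400 kb), 200 genes, and planted regions with
full ground truth. The genome is a grid of 20 kb cassettes, each holding a
TSS (with active-promoter states around it), three enhancer slots placed
> 5 kb from every TSS, and fixed filler segments so all eight states
occur; the rest is quiescent. Because carrier samples share identical
enhancer coordinates, the consensus regions recovered by the catalogue
coincide exactly with the planted intervals — which is what lets every
downstream stage be scored against truth.

Default design, chosen once as a realistic desk-scale cohort:

| parameter | default | meaning |
|---|---|---|
| planted gained | 60 | tumor-only enhancers, carriers cycling 2…10 of 10 tumors |
| planted lost | 20 | normal-carried enhancers, 8× H3K27ac in normals |
| background | 400 | carried by all 15 samples, no effect |
| decoys | 30 | 100–180 bp segments exercising the 200 bp filter |
| singletons | 10 | 1-carrier segments exercising the ≥2-sample rule |
| H3K27ac effect | 8-fold | multiplies carrier-tumor means of gained regions |
| NB dispersion α | 0.1 | variance μ + αμ² (Gamma–Poisson mixture) |
| TF binding prob. | 0.1 / 0.25 / 0.4 | background / ≥50% / ≥80% conservation tier |
| cancer types | 6 × 4 samples | pan fraction 0.23, N(5, 0.5) vs N(0, 0.5) |
| cells | 500/500/500 | malignant / normal epithelial / stromal |
| over-expression | 4× | signature-gene rate in malignant cells |

Planted enhancer lengths are uniform in [400, 2000] bp so the 200 bp
filter never binds for truth regions; decoys are planted separately.
Single-cell counts are Poisson with log-normal(0, 0.3) per-cell library
factors over log-normal per-gene rates; "expressed" is count > 0. The
differential-recovery experiments use a separate count-level simulator
(2000 regions, 60 planted 8-fold in all 10 tumors) so recall is measured
at the published design rather than at the mixed-conservation cohort,
where low-carrier gained regions legitimately stay under the fold-change
threshold.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: genome sequence and mappability, copy-number
structure, correlated noise between neighbouring regions, sample-specific
segmentation error, doublets/ambient RNA in the single-cell matrix, and
batch effects across accessibility panels.

## Problem sizes and determinism

All simulations are seeded; every stage that consumes randomness takes an
explicit seed or Generator, and a fixed seed reproduces outputs
bit-for-bit (the fixture writer round-trips byte-identically). The test
suite and the acceptance script run at toy scale — 4 Mb genomes, 2000
count regions, 1000 permutations, 200 calibration replicates, 1500 cells —
sizes chosen so the full analysis replays in well under a minute while
leaving the statistical contracts (calibration bands, recovery rates)
tight enough to be meaningful.

## Known limitations

* The Welch-on-log-counts test loses power versus a tuned count model at
  very small group sizes or very low counts; thresholds, not the test
  statistic, are the fidelity target here.
* The pan-accessible rule (2-cluster cut + pooled-median membership) is an
  explicit operationalisation of what is, in practice, a judgement made on
  a clustered heatmap; different cut heights can move borderline rows.
* Empirical p-values are bounded below by 1/n_perm (or reported as 0 by
  the plain-count convention); genome-wide multiplicity of such tests is
  not addressed.
* Interval logic is strand-agnostic by design; analyses requiring strand
  (e.g. directional TSS windows) are out of scope.
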
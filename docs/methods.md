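# Methods

## Problem and model

A pooled single-cell genomic library mixes cells from K donors. Each donor
carries a private complement of homoplasmic mitochondrial substitutions
(germline variants, VAF ≈ 1 in every cell of that donor), because mtDNA is
maternally inherited and effectively clonal within an individual. The task
is to assign each cell barcode to a donor and to flag barcodes that contain
two cells of different donors (cross-genotype doublets). Same-genotype
doublets are invisible to any genotype-based method and are out of scope;
with N equally mixed donors they are an expected 1/N of all doublets.

### Variant calling

Bases on the mitochondrial contig (rCRS numbering, 1-based, 16,569 bp) are
tallied per position and per cell barcode after removing duplicate,
secondary and supplementary alignments and bases under a Phred floor
(default 20; configurable — the calling thresholds below are the method's
published values, the quality floor is ours). A candidate SNV at a position
requires, in the pooled ("bulk") pileup:

* depth ≥ 8 (`min_depth`),
* ≥ 2 reads supporting the alternative base (`min_reads2`),
* VAF ≥ 1% (`min_var_freq`),
* bulk VAF strictly inside (1%, 99%).

The open window encodes pooling: a variant private to one of K donors has
bulk VAF ≈ 1/K, whereas VAF ≈ 0 or ≈ 1 is either noise or carried by
everyone and useless for separation. Indels and strand are ignored; each
(position, alt) pair is an independent record.

### Count matrices and missingness

`ref_counts`/`alt_counts` are cell × variant integer matrices;
`freq = alt/(alt+ref)` with NaN where depth is zero. Zero depth is recorded
as *missing*, not 0: the germline filter's denominator counts "cells with a
non-zero VAF" among observed cells, and conflating unobserved with
reference would change it. For clustering only, missing is imputed as 0
(a cell without a donor's variants behaves like reference); the imputation
value is configurable.

### Germline selection, clustering, specific sets

A variant passes the germline filter when

    |cells with VAF > 0.99| / |cells with VAF > 0|  >  0.5

over non-missing cells ("VAF above 99%" is strict `> 0.99`, "non-zero" is
strict `> 0`; both boundaries configurable). Cells are clustered on the
retained VAF matrix with K-means (max_iter = 1000, tol = 1e-5, n_init = 10,
Lloyd iterations, fixed seed 42) or a diagonal-covariance Gaussian mixture.
Within each cluster the same homoplasmy-majority rule, restricted to the
cluster's cells, yields a raw variant set; variants occurring in ≥ 2 sets
are removed (strict sample-specificity; `max_occurrence=2` gives the
more permissive reading where variants shared by exactly two sets
survive). A cluster left empty is a hard model degeneracy: rerun with a
different K or use direct mode.

**Carrier-prevalence floor.** The pipeline additionally requires a
cluster-set variant to be seen (VAF > 0) in ≥ 25% of the cluster's covered
cells (`min_carrier_fraction`, pipeline default 0.25; the bare operation
defaults to 0). Rationale: a germline variant of the cluster's donor is
carried by every cell, so its carrier fraction among covered cells is ≈ 1.
At shallow coverage (~1×) a single doublet or error read produces a
per-cell VAF of exactly 1.0, and with a denominator of one or two cells the
majority rule passes; without the floor these artifacts flood every
cluster's raw set at 250 reads/cell and the common-variant removal then
empties all sets. The floor only excludes variants carried by a small
minority of a cluster, which cannot be that cluster's germline markers.

### Silhouette estimation of K

When the number of pooled donors is unknown, K is chosen as the argmax over
a candidate range of the mean silhouette score of the K-means labels (ties
to the smaller K). This is reliable on singlet-dominated data; a large
doublet fraction inflates the apparent cluster count because doublet
profiles form their own small groups, so K estimation is best run before or
without doublets in mind, and a known pool size should be preferred when
available.

### Beta-binomial doublet model

For cell *c* and cluster *i* with specific set G_i, let A₁/A₀ be the summed
alternative/reference counts over the variants of G_i observed in *c*
(unobserved variants contribute nothing). A₁ ~ Binomial(A₁+A₀, p) with a
conjugate Beta(α_i, β) prior, β = 1 and

    α_i = 1 + mean over G_i of ( mean alternative count among cluster-i cells ),

i.e. the prior pseudo-count tracks the typical per-variant coverage of a
true carrier. The score is the posterior mode

    p = (α + A₁ − 1) / (α + β + A₁ + A₀ − 2),

undefined (missing) only for the uniform prior with no data. `p1` is the
score against the cell's first-fitted cluster — its initial clustering
label, falling back to the best-scoring cluster if that set is uncovered in
the cell; a flag switches to argmax throughout. `p2` is the best score
among the remaining clusters, each evaluated with its own α_j.

Classification: Singlet if p1 > 0.99 and p2 < 0.01; Doublet if p1 < 0.8 or
p2 > 0.2; remaining cells take the majority label of their 5 nearest
labeled neighbours (Euclidean on raw (p1, p2) — both axes already live in
[0,1]). The pipeline defaults to `trust_p1`: any cell with p1 > 0.99 is a
Singlet regardless of p2, because a high p2 next to a near-1 p1 is more
plausibly a shared somatic variant than a second genotype. This matters
quantitatively: since α − 1 ≈ per-variant coverage, a pure singlet's score
against a foreign cluster has a prior floor of (α_j − 1)/(α_j − 1 + A₀) —
a few percent at realistic coverage, so the strict p2 < 0.01 rule labels
essentially no singlets and would leave the KNN step with a single class.
The thresholds themselves are the published defaults and are configurable,
not silently altered. Known limitation: for clusters with very few specific
variants (≈ 5) the same prior floor approaches the 0.2 doublet bound, and a
small fraction of true singlets whose p1 dips just below 0.99 (one or two
error reads) can be miscalled as doublets; this is a property of the
printed prior/threshold combination, measured in the acceptance suite.

Singlets are assigned to their argmax-p cluster (ties to the lower index,
with a warning); doublets carry their (first-fitted, second) cluster pair;
cells covering no specific variant of any cluster are reported
`unassigned`, never silently dropped.

### Direct mode

When cells are hard to cluster (extreme shallowness, very imbalanced
pools), the variants are clustered instead: germline-filtered columns are
grouped into K sets by K-means on their across-cell VAF profiles, each
group plays the role of a donor's specific set, and scoring proceeds with
first-fitted = argmax p. α needs per-cluster cells that direct mode does
not define, so provisional labels are taken as each cell's best mean
observed VAF across groups (falling back to all cells for a group with no
provisional members); this choice only scales the prior.

## Synthetic-data generator

The generator emulates a pooled mtscATAC-seq-like experiment at the
allele-count level:

* **Haplotypes.** Each donor draws a private set of variants (default 5–30,
  sampled per donor) plus optional variants shared by ≥ 2 donors; positions
  are drawn without replacement from the 16,569 bp circle. The 5–30 range
  is a realistic stand-in for the homoplasmic differences between unrelated
  individuals.
* **Depth.** Per-cell, per-variant depth is Poisson with mean
  `reads_per_cell × 4/1000` — calibrated so 1000 mitochondrial reads per
  cell correspond to ~4× mean per-site coverage.
* **Errors.** Alleles flip between alt and ref as Binomial(depth, 0.002), a
  typical Illumina substitution rate.
* **Doublets.** A chosen fraction of output barcodes are the exact
  elementwise sums of two uniformly chosen parent cells (parents removed),
  so same-donor doublets occur at the expected 1/N rate. The truth table
  records every origin.
* **Read level.** An optional toy SAM (single-base reads, CB tags, one read
  per counted allele) plus a synthetic reference FASTA lets the pileup and
  calling modules run end to end; it deliberately reproduces the count
  matrices exactly and models no fragment-length, duplicate or Tn5
  structure.

What the generator does *not* emulate: correlated coverage along the
genome, NUMT contamination, strand artifacts, heteroplasmy drift, library
level depth variation between donors. Passing tests therefore demonstrate
the statistical machinery under the stated model, not robustness to every
artifact of real libraries.

## Evaluation

Accuracy maps predicted clusters to truth donors by maximum-weight
bipartite matching on the singlet contingency table, with "doublet" as its
own class. ARI is the pair-counting adjusted Rand index. Doublet detection
is scored with p2 (AUC) and threshold calls (TPR = detected true doublets /
true doublets; FDR = false calls / calls, 0 when none); same-genotype
doublets are excluded from these detection benchmarks since the method is
blind to them by construction and the reference simulation design pools
cross-genotype doublets only. Concordance tables are row-normalised
percentages over the barcode intersection, excluding cells unassigned by
either labeling.

## Problem sizes and determinism

The acceptance benchmarks use 8 donors × 100 cells (250/1000/2000
reads/cell) and 8 × 500 cells (2000 reads/cell), 5 replicates where a mean
is reported; one replicate simulates, fits and evaluates in a few seconds
on one core. All randomness (haplotypes, counts, K-means, replicate seeds)
derives from a single user seed via `numpy.random.SeedSequence`; reruns
with the same seed are byte-identical.
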
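# Methods

This note documents the model implemented by `hgsoc_strat`, the default
parameters and why they were chosen, the design of the synthetic
generator, the numerical conventions, and known limitations. It makes
no empirical claims beyond what the test suite computes.

## 1. Genomic signature: LST counting

A copy-number profile for a sample is a set of per-chromosome segments
in 1-based closed coordinates, each carrying a total copy number and
optionally a major-allele copy number. The segment *state* is the pair
(total, major); when major-allele calls are absent the state degrades
to total copy number only (a single warning is emitted per run).

**Smoothing.** Adjacent segments in the same state are merged. Then,
iteratively, the shortest segment under 3 Mb (`min_variant_mb`) is
deleted — ties broken by genomic position — and its neighbors re-merged
if they now share a state. The loop ends at a fixed point: no sub-3 Mb
segment remains whose removal changes the segmentation. The procedure
is deterministic and idempotent (property-tested).

**Counting.** A large-scale state transition (LST) is a breakpoint
between two adjacent smoothed regions each spanning at least 10 Mb
(`min_region_mb`). A change in either total or major-allele copy number
counts. Breakpoints are never counted across chromosome ends; when
centromere intervals are supplied, chromosomes are split into arms
first and segments spanning the centromere are truncated at it, so
pericentromeric breakpoints are not counted either.

**Ploidy and cutoffs.** The DNA index is the length-weighted mean total
copy number divided by 2 (so a uniform diploid genome has index 1.0).
Index ≥ 1.3 (`DNA_INDEX_THRESHOLD`) calls the genome near-tetraploid.
The LST count is dichotomized at 15 breakpoints for near-diploid and 20
for near-tetraploid genomes; reaching the cutoff yields `LST_high`, the
surrogate for homologous-recombination deficiency.

## 2. Transcriptomic signature: clustering and naming

The expression matrix (genes × samples) is restricted to the signature
genes; at least 50 % of each scheme's genes must be present unless the
caller forces the match. Each gene is z-scored across samples
(population standard deviation, ddof = 0); zero-variance genes are
dropped. Samples are clustered with Ward's method on Euclidean
distances by default (`scipy` linkage on a condensed distance matrix —
the `ward.D2` convention), or on 1 − Pearson correlation. The
dendrogram is cut at k clusters (k defaults to the number of gene sets
in the scheme). Gene and sample orders are canonicalized before
clustering so results are invariant to input order.

Cluster identities are arbitrary, so clusters are *named*: for every
(cluster, gene-set) pair the mean z-score of the set's up-genes within
the cluster is computed, and clusters are matched to set names
greedily, largest score first, each name used once. If a cluster's
scores are all tied the configuration is ambiguous and an error is
raised rather than guessing.

Supporting checks: a concordance cross-tabulation of two assignments
on their common samples, and a PCA-based association test (two-sided
Mann–Whitney or Welch on the leading components between groups) to
verify that a discovered split is carried by the signature genes.

## 3. Stratification

The genomic and transcriptomic calls are combined on the intersection
of samples with both calls into cross-product strata
(`LST_high/Fibrosis`, `LST_high/non_Fibrosis`, `LST_low/Fibrosis`,
`LST_low/non_Fibrosis`). An empty intersection is an error.

## 4. Statistics

**Fisher's exact test.** 2×2 tables use the point-probability
two-sided test (scipy; the same convention as R's `fisher.test`).
Larger 2×c tables with total n ≤ 1000 use an exact full enumeration of
all tables with the observed margins: cell probabilities are computed
with log-gamma, and tables whose log-probability is at most that of the
observed table plus log(1 + 1e-7) are accumulated (the relative
tolerance guards against floating-point ties, mirroring R). Above
n = 1000 a Monte-Carlo estimate over Patefield-sampled tables with
fixed margins is used and the method is labeled accordingly. Tables
with a zero margin are rejected.

**Survival.** Kaplan–Meier curves, median survival, the k-group
log-rank test (χ², k − 1 df), and Cox proportional-hazards models with
Efron tie handling are delegated to `lifelines`. Pairwise group
comparisons are Benjamini–Hochberg adjusted (`statsmodels`,
`fdr_bh`). Follow-up is administratively censored at a 120-month
horizon by default: longer times are truncated to 120 with the event
indicator set to 0. Cox fits are complete-case: records missing any
modeled covariate (marker `NA`) are dropped; categorical covariates
enter as dummies against an explicit reference level; 95 % CIs are
Wald, exp(β ± 1.96 SE).

Note that the BH step-up adjustment is *not* idempotent — re-adjusting
an already adjusted vector can change it (e.g. [1.0, 0.125] → [1.0,
0.25] → [1.0, 0.5]). The tests therefore assert the closed-form step-up
with cumulative minima, adjusted ≥ raw, and rank-order preservation.

**Association report.** Each clinical variable is cross-tabulated
against the group labels on its non-missing samples; variables with a
single observed level are skipped; column percentages and the Fisher p
accompany each table.

## 5. Synthetic generator

The generator plants ground truth that every stage can be scored
against; its defaults are the study conditions and were fixed before
the stochastic acceptance criteria were run.

**Copy-number profiles.** Exactly `n_lst` transition breakpoints are
distributed over chromosomes subject to a capacity of
`chromosome_length // 10 − 1` breakpoints per chromosome (every
flanking region ≥ 10 Mb). Within a chromosome, breakpoints are placed
by sorted-uniform offsets added to minimal 10 Mb spacings. Copy number
alternates around the baseline (2 or 4) by ±1, with the deviation
direction alternating by chromosome parity so the genome-wide DNA
index stays at baseline/2 and never drifts across the 1.3 ploidy
threshold. Sub-3 Mb variant regions (0.5–3 Mb, state ±1 relative to
the host) are inserted only where the host segment keeps ≥ 3 Mb on both
sides; shortest-first smoothing therefore always removes exactly the
variants and restores the planted geometry, making the planted LST
count recoverable bit-exactly (property-tested over random
configurations). Infeasible requests (count exceeding capacity) are
rejected.

**Expression.** Signature genes plus background genes get independent
standard-normal noise (σ = `noise_sd`, default 1.0); each group's
up-genes are shifted by `shift × noise_sd` (default 2.0). This is the
separation regime at which the classifier's median adjusted Rand index
is asserted ≥ 0.9.

**Survival.** Times are exponential proportional hazards: baseline
hazard ln 2 / 60 per month (median 60 months at baseline) times
exp(planted log-HR). The planted effects are additive: log 2.2 for
`LST_low` and log 1.5 for `Fibrosis`, taken from the multivariate
overall-survival model of the published cohort. Censoring is an
independent exponential with rate μ = q/(1 − q) · λ̄ targeting a
censoring fraction q (default 0.3), plus administrative censoring at
the 120-month horizon.

**Cohort.** Four strata × 50 samples by default, 22 chromosomes of
150 Mb, 40 % of samples tetraploid-baseline, 200 background genes, and
stage/debulking covariates drawn with group-dependent frequencies. The
cohort writes itself as `segments.seg`, `expression.tsv`,
`signatures.gmt`, `clinical.csv` and a `truth.json` sidecar; identical
seeds give byte-identical files.

**Realism limits.** Chromosomes are equal-length with no arm structure
by default; copy numbers deviate at most ±1 from baseline (no focal
amplifications, no whole-arm events); expression noise is homoskedastic
and genes are independent; hazards are exactly proportional and
censoring is independent. These idealizations are intentional: they
make planted truth exactly recoverable so any mismatch indicts the
implementation, not the data.

## 6. Numerical conventions

* Coordinates are 1-based closed; segment length is end − start + 1.
* Smoothing deletion ties (equal lengths) break by genomic position.
* Ward linkage uses the condensed-distance (`ward.D2`) convention.
* Z-scores use population variance (ddof = 0).
* Median dichotomization sends ties (= median) to the *low* group.
* A DNA index of exactly 1.3 is near-tetraploid (≥, not >).
* Cox ties use Efron's approximation (the `lifelines` default).
* Published p-values are asserted to one unit in their last printed
  digit, the finest tolerance the printed precision supports.
* Exact-vs-Monte-Carlo Fisher switch at n = 1000; derived RNG seeds
  are drawn below 2³¹.

## 7. Limitations

* The LST caller requires segmented input; it performs no segmentation
  of raw coverage and no purity/ploidy deconvolution — DNA index is
  computed from the provided integer copy numbers.
* Without major-allele copy numbers, copy-neutral LOH transitions are
  invisible and the LST count can be underestimated.
* The four-group naming scheme requires each cluster to elevate some
  gene set; degenerate clusterings raise rather than label arbitrarily.
* The exact 2×c Fisher enumeration is exponential in c; it is bounded
  to 2-row tables with n ≤ 1000, beyond which the Monte-Carlo p has
  sampling error (reported with its replicate count).
* The published reference tables allow verifying the association layer
  only; the survival figures of the original cohort are not
  reproducible from counts alone and are represented instead by the
  planted-hazard synthetic cohort.
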
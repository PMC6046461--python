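# Methods notes

This document records the statistical models, the defaults and why
they were chosen, what the synthetic data does and does not emulate,
and the numerical corner cases.

## Differential expression

The DE stage follows the classic two-group exact-test workflow for
small-n bulk RNA-seq.

*Filtering.* Genes with a mean count below 10 reads per sample across
all samples are removed before testing. The rule is inclusive at the
boundary (mean exactly 10 is kept) and idempotent.

*Normalization.* Trimmed mean of M-values against the sample whose
upper-quartile count is closest to the mean upper quartile; 30%
two-sided trim on M, 5% on A, over genes expressed in both samples;
factors rescaled to geometric mean 1. Counts are then scaled to the
geometric-mean effective library size ("pseudo-counts") before exact
testing — a documented simplification of the quantile-conditioning
adjustment used by the reference edgeR implementation.

*Dispersion.* Method-of-moments, pooled within groups via the ratio
estimator Σw(var−μ)/Σwμ². Three modes:

- `common` — one φ for the whole matrix;
- `trended` (default) — the pooled estimator within ~100-gene
  abundance bins, interpolated per gene on the log-mean axis;
- `shrunk` — gene-wise estimates pulled toward the trend with 20
  prior degrees of freedom.

The trended default matters: real count data (and the simulator,
φ = φ₀ + slope/μ) are more dispersed at low abundance, and a common
φ makes low-abundance tests anti-conservative (empirically ~12% null
rejections at α = 0.05 versus ~5% for the trend).

*Exact test.* Conditioning on the total of the two group sums, group
sums are NB with means n_j·μ and dispersion φ/n_j; the two-sided
p-value is the conditional probability of all splits whose point
probability does not exceed the observed one. At φ = 0 this is the
conditional binomial test, which serves as an oracle in the tests.
log2 fold changes use a 0.5 prior count on normalized group means so
zeros stay finite.

*Ranking metric.* `sign(log2FC)/p`, with p floored at the smallest
positive observed p (never below 1e-300) so scores stay finite; a
zero log2FC gives score 0. Ties are broken by |log2FC| descending,
then lexical gene id, so downstream orderings are deterministic.

## Pre-ranked enrichment

Weighted-KS running sum with gene-label permutation. The null for a
set of k listed members is the ES of random k-subsets of the list
(shared across equal-sized sets); p uses the plus-one estimator, so
it is never 0 and never below 1/(B+1). NES divides ES by the mean
magnitude of same-sign null ES. FDR is Benjamini–Hochberg on the
permutation p-values — simpler than NES-stratified FDR; NES is still
reported.

Two deliberate choices:

- *Gene-label rather than sample permutation*: with n = 4 per group
  the sample-permutation null is degenerate (35 distinct splits).
- *Weight exponent 0 (classic KS) by default.* The signed inverse-p
  metric spans hundreds of orders of magnitude; with weight 1 the
  top-ranked gene dominates the normalizer, so any random set
  containing it reaches |ES| ≈ 1 and planted signals become
  inseparable from the null. The classic statistic uses only member
  positions and keeps full power; weight 1 remains available for
  tamer metrics and is exercised by the worked hand examples.

Sets with fewer than 10 or more than 500 listed members are excluded
(common practice; the size window is configurable).

## Gsheat

Per sample, genes are ranked ascending by raw count with average
ties, so each sample's ranks sum to exactly N(N+1)/2; a set's score
is the sum of its members' ranks, bounded by [k(k+1)/2,
k(2N−k+1)/2]. Average ties preserve the conservation identity
exactly, and rank invariance under per-sample monotone transforms
means CPM scaling or log transforms cannot change any score — which
is why raw counts are used directly and no normalization step exists
in this path. Gross library-size differences can still alter tie
structure between samples; this is accepted and surfaced by tests
only through the conservation identity.

Scores are reported raw (the definition) and normalized by the null
expectation k(N+1)/2 (aids cross-set comparison; 1.0 = no
activation).

Differential sets use a moderated t: per-set pooled variances are
shrunk toward a prior (d₀, s₀²) estimated across sets by moment
matching of log-variances (digamma/trigamma inversion, the standard
empirical-Bayes construction); the statistic is referred to a t
distribution with d₀ + d degrees of freedom. With fewer than 10 sets
the prior is not estimable and the ordinary pooled t is used. The
heat map z-scores each row across samples and clusters rows and
columns with average-linkage Euclidean hierarchical clustering
(display choices; the unscaled ordered matrix is returned for
testing). The enrichment-map export writes significant sets as nodes
and Jaccard overlaps ≥ 0.25 as edges.

## Two-dimensional enrichment

Ranks within each contrast ascend from most down- to most
up-regulated; genes missing from either contrast are dropped and
counted. The per-axis set score is the scaled mean-rank displacement
s_d = 2(R̄_d − (N+1)/2)/N — bounded, signed, and zero in expectation
under random membership. This formula is this package's concrete
choice of multi-contrast rank statistic; it is the largest
interpretive decision in the package and is therefore pinned down by
direct formula tests.

Significance: two-sample Hotelling T² of member vs non-member 2D
rank vectors with the F approximation (default; deterministic and
well calibrated at set sizes ≥ 10), or a member-label permutation
null on the displacement magnitude. The permutation engine is the
reference oracle; the two agree in rank order (Spearman ≥ 0.9 in
tests, ≈ 0.999 observed). A singular pooled covariance (perfectly
correlated contrasts) triggers a fallback to permutation with a
warning.

Quadrant classification gates each axis on |s| ≥ 0.1 **and**
|s| ≥ 2·sd(s) where sd(s) = √((N+1)(N−k)/(3kN²)) is the
random-membership standard deviation. The second gate exists because
sd(s) ≈ 1/√(3k) is itself ≈ 0.1 at k ≈ 30: without it, sampling
noise on the inactive axis routinely promotes contrast-specific sets
to "discordant". The miRNA-target mode is the same computation on a
target-set collection plus a count of sets in the significant
down-down corner.

## Phenotype statistics from summaries

The 2×2 factorial ANOVA is fully determined by per-cell (mean, SEM,
n): within-cell SS is Σ(n_i−1)·n_i·SEM_i² (since SD = SEM·√n), and
the between-cell structure is fit by n-weighted least squares on the
four cell means with effect (sum-to-zero) coding. Each effect's Type
III SS is the increase in weighted residual SS when that column is
dropped with the interaction retained — matching the commercial
packages typically used on such tables, and differing from Type I
only when cell sizes are unbalanced. %variation = 100·SS/SS_total
with SS_total = between + within; percent shares sum to 100 exactly
only in balanced designs (a property test covers this). Any full
dataset realizing the summaries gives identical results, which the
tests exploit by affine-adjusting random draws to exact mean/SD and
comparing against a standard full-data Type III ANOVA at machine
precision.

The Welch t from summaries is t = Δmean/√(SEM₁²+SEM₂²) with
Welch–Satterthwaite df; it equals the full-data Welch test on any
realizing dataset.

Reproduction tolerance for printed tables is ±2 percentage points of
%variation, reflecting two-significant-digit rounding of printed
means and SEMs.

## Synthetic data

The generator emulates the study design, not its biology:

- groups young-sham n=6, young-DOCA / aging-sham / aging-DOCA n=4;
- log2-normal baseline expression (location 5, scale 2 → median ~32
  counts, heavy right tail);
- NB counts via gamma–Poisson with φ = φ₀ + slope/μ, defaults
  φ₀ = 0.05, slope = 2 — conventional values for bulk tissue
  RNA-seq; the study supplies no dispersion estimates, so these are
  conventions, not calibrations;
- log-normal library-size offsets (sd 0.25 on log2);
- 5% DE genes per contrast at |log2FC| = 2 on the treatment factor
  within each age stratum, signs balanced; a mild age main effect
  (sd 0.1 log2 on 10% of genes) so the factorial structure exists;
- per contrast, 3 activated sets whose members shift coherently by
  1 log2 unit in the DOCA samples of that stratum.

Activated sets are drawn before DE genes, and DE genes are drawn
from outside the activated sets' members. This keeps ground truth
attributable: a "young-activated" set must not, by lot, also carry
aging DE genes, or its truth label (contrast-1-specific) would be
wrong and recovery unmeasurable.

Default test scale is 2,000 genes and 100 sets of size 10–50 —
small enough for permutation experiments in seconds, structured like
the full ~14,000-gene post-filter matrix (a full-scale mode is just
`n_genes=14410`). One integer seed drives everything through
deterministically spawned sub-streams; identical configurations are
byte-identical.

What the simulator does **not** model: batch effects, sample
outliers, correlated genes outside planted sets, compositional
(transcriptome-share) artifacts, and GC/length biases. Passing tests
therefore demonstrate statistical correctness and calibration under
the NB factorial model, not robustness to those real-data pathologies.

## Pipeline

One global seed is fanned out per stage via spawned seed sequences,
so any stage can be re-run in isolation with unchanged results. All
inter-stage artifacts are TSV; the manifest records a configuration
hash (excluding the output directory), per-stage wall time and
SHA-256 checksums of every output. Stage logs report gene and set
counts at every filter so the funnel (input genes → post-filter →
significant) is visible in every run. Default problem sizes (2,000
genes, 100 sets, 1,000 permutations) complete the full pipeline in a
few seconds on one CPU.

## Known limitations

- The exact test assumes the estimated dispersion is known; no
  quasi-likelihood or robust trend fitting, no GLM covariates.
- Enrichment FDR is BH on permutation p-values, not NES-stratified.
- The 2D significance engines test member-vs-nonmember location
  shift; a set covering most of the universe is untestable.
- Printed-table ANOVA reconstruction assumes a single-timepoint
  two-factor design; rows produced by repeated-measures fits will
  not reproduce and are out of scope.
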
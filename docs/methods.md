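# Methods

`persistsig` re-implements, as a tested library, the statistical machinery
used to detect and exploit treatment-persistent tumor-cell signatures:
per-sample gene-set enrichment scoring, per-cell/per-spot module scoring
with percentile high-score calls, housekeeping-null calibration of spatial
thresholds, cluster taxonomy across treatment conditions, flank-normalized
read-distribution profiling around genomic sites, hypergeometric attribute
enrichment with TF-target attribution, and survival stratification.  All
of it is exercised end to end on synthetic data with known ground truth.

## Per-sample enrichment scores (`persistsig.gsva`)

The score of signature *k* in sample *j* is a nonparametric, unsupervised
measure of how concordantly the signature's genes sit at one extreme of
the sample's expression profile.

1. **Scale normalization (counts only).** Each sample is rescaled so that
   its 75th percentile over its nonzero genes equals the geometric mean of
   all samples' 75th percentiles.  The geometric-mean target was a design
   choice: any common target yields the same downstream ranks, and the
   geometric mean keeps the normalized matrix on the scale of the input.
   In *cohort mode* genes with a zero count in any sample are removed
   first, the convention used for large tumor cohorts where such genes are
   unstably measured.
2. **Kernel CDF transform.** Gene *i*'s value in sample *j* is mapped to a
   smoothed empirical CDF estimate across the n samples: Poisson kernels
   for counts, `F_ij = (1/n) Σ_k PoisCDF(x_ij; λ = x_ik + 0.5)`, Gaussian
   kernels for log-normalized data,
   `F_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)` with per-gene bandwidth
   `h_i = sd_i/4` (floored at `1e-8·(1+|mean_i|)` so constant genes map to
   exactly 0.5).  These are the standard estimator choices for this
   family of methods; the continuity offset 0.5 keeps the Poisson kernel
   defined at zero counts.
3. **Rank centering.** Within each sample the transformed values are
   ranked ascending and shifted by `(p+1)/2`, so the centered ranks sum
   exactly to zero.  Dense integer ranks with a deterministic tie-break
   (lexicographic gene id) are used instead of fractional average ranks:
   the walk normalization below assumes an integer rank multiset, and the
   tie rule makes scores reproducible to the bit.
4. **Random walk.** Genes are laid out from most to least expressed
   (decreasing centered rank, ties again by gene id).  Walking down this
   list, an in-set gene advances the in-set sum S1 by its `|r|^τ` share
   (τ = 1 by default) and an out-of-set gene advances S2 by `1/(p − m)`.
   ES⁺ is the largest positive and ES⁻ the most negative deviation of
   S1 − S2; the reported score is `|ES⁺| − |ES⁻|`.  This
   magnitude-difference convention rewards sets acting concordantly in a
   single direction: a set with strong members in both directions has
   large ES⁺ *and* large |ES⁻| and scores near zero.  The alternative
   maximum-deviation convention is available behind an option.

Scores are bounded in [−1, 1], invariant to gene-row order, equivariant
under sample permutation, and anti-symmetric under rank negation on
tie-free inputs; the test suite checks all four properties and verifies
the full pipeline against an independently written loop-by-loop
transcription of the definitions to 1e−10.

## Module scores and high-score calls (`persistsig.scoring`)

The per-cell (or per-spot) score of a signature is the mean log-normalized
expression of its genes minus the mean expression of expression-matched
control genes: genes are binned into 24 quantile bins of pooled mean
expression and each signature gene draws 100 controls from its own bin
(without replacement when the bin is large enough, with replacement
otherwise).  This cancels the depth/abundance component, so a set of
merely highly expressed genes scores near zero.  Setting `n_ctrl=0` gives
the plain signature-mean score used where a simple average is wanted.

"High" calls use a linear-interpolation (type-7) percentile threshold on
the score vector, 90th percentile by default, with *at or above* counting
as high.  The flagged-count invariant (`floor(n(1−q/100))` or one more)
is tested.

## Housekeeping-null calibration (`persistsig.calibration`)

A percentile threshold on spot scores is only meaningful if random
signatures of stably expressed genes rarely exceed it.  The calibration
scores the query signature over all spots, takes its 90th percentile as
the candidate threshold, scores `n_null_sets` (default 100) length-matched
random sets drawn from a housekeeping pool, and reports the pooled
fraction of (spot, null-set) scores at or above the candidate threshold.
The calibration passes when this achieved null exceedance is ≤ the
allowed false-positive rate (5%).  Pooling over all (spot, null-set)
pairs — rather than per-set summaries — operationalizes the exceedance
directly as a spot-level false-positive rate.

Control-subtracted module scores are essential here: the plain mean score
of a gene set depends on its genes' absolute expression, and housekeeping
genes are by construction highly and stably expressed, so plain means of
query and null sets are not on a common scale.  With bin-matched control
subtraction both distributions are centered at zero under the null, and a
query drawn from the pool itself achieves ≈ 10% exceedance (the 90th
percentile of an exchangeable score vector) and fails the 5% gate — the
behavior that makes the calibration honest.  An optional minimum
read-count spot filter (e.g., ≥ 500 counts) can be applied before
scoring.

Spot-cluster comparisons of high/low proportions use a 2×2 Pearson
chi-square without continuity correction (a single documented convention,
checked against the textbook formula).

## Cluster taxonomy (`persistsig.taxonomy`)

Clusters observed across a treatment course are labeled *initial*
(dominated by parental-like samples), *induced* (dominated by resistant
samples), or *persistent* (similar proportions everywhere).  Dominance is
assessed on within-sample proportions renormalized across samples — using
raw counts instead would let a deeply sampled condition dominate every
call.  Defaults: dominance share ≥ 0.7, similarity coefficient of
variation ≤ 0.5; both are exposed, and persistent calls whose CV exceeds
the similarity threshold carry a `borderline` flag.  The published
category assignment this emulates was qualitative; this quantitative rule
is a declared substitute, not a reconstruction, and its forced cases
(cluster present only in one group; cluster exactly uniform) are pinned
by tests.

## Read-distribution profiles (`persistsig.readdist`)

Reads (5′ ends; strand-aware) are counted in 21 bins of 100 bp centered
at offsets −1000…+1000 around each site's integer midpoint, averaged
across replicates.  An odd symmetric layout was chosen so "the value at
position 0" is one well-defined bin.  Profiles are normalized by the mean
of the two outermost bins — pooled across sites by default (an
average-profile convention robust to zero-heavy per-site flanks), per
site on request.  Normalization is idempotent and scale-invariant.
Conditions are compared with a Welch t-test on per-site normalized center
values (sites as the replication unit; the per-replicate alternative is a
caller choice), and per-anchor enrichment scores (e.g., at TSSs) with the
two-sided Wilcoxon rank-sum test.

## Enrichment statistics (`persistsig.enrichment`)

Attribute enrichment in a foreground region set against a background
universe uses the one-sided upper-tail hypergeometric test, exact against
full draw enumeration for all universes ≤ 12 regions.  When GC matching
is on, the background is resampled with replacement to the foreground's
GC decile distribution (10 bins, seed-controlled) before testing — an
explicit, testable stand-in for "accounting for sequence composition".
P-values are Benjamini–Hochberg adjusted across attributes (enriched at
adjusted p < 0.05); differential tables are filtered with the three-part
rule (Bonferroni-adjusted p < 0.01, detection fraction ≥ 10%,
|log-FC| ≥ 0.25 for expression; p < 0.05 for accessibility).

TF-target attribution reports, per cluster, the fraction of its
differential genes that are targets of at least one enriched TF; a gene
targeted by t enriched TFs contributes 1/t to each, so the per-TF
decomposition sums exactly to the covered fraction.  The stacking rule
for shared targets is a declared choice.

## Survival stratification (`persistsig.survival`)

Single-signature stratification splits samples at the median score, with
*strictly above* counting as high (the median sample goes low; documented
and tested).  Multi-signature stratification clusters samples on
Euclidean distances between their score vectors with complete-linkage
agglomeration and cuts the tree at two branches; complete linkage was
chosen for determinism without centroid arithmetic, with average and
Ward-style linkage behind a flag.  Groups are compared with Kaplan–Meier
curves (delegated to lifelines, cross-checked against a hand
product-limit oracle) and a directly implemented two-group log-rank test
(observed-vs-expected events over pooled event times, hypergeometric
variance, χ² with 1 df), cross-checked against both an enumeration oracle
and lifelines.  Simulations verify a type-I error within [0.03, 0.07] at
α = 0.05 and power ≥ 0.85 at hazard ratio 2 with 100 subjects.

## Synthetic data (`persistsig.simulate`)

The generators produce the statistical structure the analyses assume, and
nothing more:

* **Cell/spot counts**: negative binomial with variance
  `μ + μ²/dispersion` (dispersion 2, heavy-tailed as in droplet
  scRNA-seq), per-gene lognormal size factors (σ = 0.5, about a 10-fold
  5th–95th percentile spread), baseline mean 5 counts.  A planted
  fraction of units (default 10%) has the signature genes' means
  multiplied by `2^log2_effect`.  Spatial spots lie on a grid with
  contiguous cluster bands; cluster 1 carries the planted shift.
* **Housekeeping pool**: the 5% of genes with the lowest empirical
  coefficient of variation (planted genes excluded), mirroring the role
  of a curated stable-gene atlas without requiring one.
* **Pileups**: Poisson bins at a background rate with the center
  multiplied by the enrichment factor under a Gaussian taper (sd 150 bp),
  so the flank-normalized center recovers the factor by construction.
* **Cohorts**: exponential event times with the hazard multiplied for the
  planted half, independent exponential censoring.

All generators are pure functions of (config, seed).  What the synthetic
data deliberately lacks: gene–gene correlation structure, ambient RNA and
doublets, spatial autocorrelation beyond the cluster bands, batch
effects, and non-proportional hazards.  Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
signal under the stated noise model — not performance on real tissue.

## Numerical choices and problem sizes

Kernel CDF values are clipped to the open unit interval at machine
precision; a signature whose in-set genes all have centered rank zero
falls back to equal walk steps; degenerate inputs (all-identical scores,
zero-margin 2×2 tables, zero flank coverage, zero events) raise errors
rather than returning silently meaningless numbers.  The test suite and
`scripts/acceptance.py` use 200 random small matrices plus a 30×8 matrix
for oracle equivalence, 1000 cells / 2000 spots for recovery and
calibration, 500 sites for profiles, 2000 null and 1000 alternative
cohort replicates (n = 100) for the log-rank operating characteristics,
and 200 replicates (n = 60) for end-to-end detection — sizes at which
every Monte-Carlo margin in the assertions is several standard errors
wide.

## Known limitations

Scores are deterministic but the Poisson-kernel stage is O(genes ×
samples²), so very large cohorts should be scored in gene blocks; the
module-score control machinery assumes enough genes per bin to draw
controls (24 bins need a few hundred genes to be meaningful); the
taxonomy rule and the GC-matching scheme are declared substitutes for
procedures their source described only qualitatively; and no multiple
hierarchical-clustering linkages are searched — the two-branch split uses
one stated linkage.
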
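# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not emulate.

## Screen model and data flow

A capture-based STARR-seq screen measures, for each ~500-bp SNP-centered
region, the abundance of its fragments in an input (plasmid) library and
an output (reporter mRNA) library, in replicate. The pipeline consumes
aligned proper read pairs (SAM) or an equivalent fragment table, retains
fragments whose outer span is 400-600 bp and which cover at least one
panel SNP, and tallies two matrices: per-region fragment counts per
library (a fragment covering k panel SNPs counts once in each of the k
regions) and per-SNP ref/alt allele counts per library. Coordinates are
0-based half-open internally; panel positions are 1-based (VCF-like) and
BED intervals 0-based half-open, with conversions centralized in the I/O
layer. Bases below the quality floor (default phred 20) or with
disagreeing overlapping mates are masked "unknown": they stay in region
counts but are excluded from the allele table. PCR-duplicate removal is
off by default (a `dedup` flag collapses identical spans).

## Activity calling

Counts are normalized by median-of-ratios size factors computed over
regions with all-positive counts. Per region the model is

    mu_ij = s_j * q_i * 2^(x_j * beta_i),    x_j = 1 for output libraries,

with NB observation noise of dispersion alpha_i. beta is estimated by
iteratively reweighted least squares (log link, weights mu/(1+alpha mu)),
vectorized across regions since the design is shared; the reported
log2FC is the unshrunk MLE, its standard error comes from the observed
information, and the Wald z = beta/SE is referred to a standard normal,
two-sided. Regions with an all-zero condition are reported missing and
classified `filtered`.

Dispersion estimation proceeds in three steps. (1) Method-of-moments
estimates on normalized counts (pooled within-condition variance,
`alpha_mom = (var - mu)/mu^2`). (2) A nonnegative trend
`alpha(mu) = a0 + a1/mu` fitted to the MoM values by trimmed
nonnegative least squares (one MAD-based trim pass). (3) A per-region
MAP estimate maximizing the Cox-Reid-adjusted NB profile likelihood (at
the fitted group means) plus a log-normal prior centered on the trend
with variance 0.25 (configurable `prior_var`), evaluated on a 60-point
log-spaced grid with parabolic refinement. The MAP-on-likelihood form
matters: shrinking the raw MoM point estimate in log space collapses
the many near-zero MoM draws that 2+2 replicates produce and inflates
the Wald tail roughly tenfold; the likelihood is flat there and lets
the prior dominate instead. The Cox-Reid term (for the two-group design,
`-0.5[log sum_in w + log sum_out w]`) removes the downward bias from
estimating two means.

Independent filtering uses a fixed mean-normalized-count threshold
(default 10), chosen for determinism and transparency over a threshold
search; filtered regions are excluded from the BH family. Classification
at BH FDR < 0.01: PRE if log2FC > 0, NRE if log2FC < 0.

Measured calibration (null screens of 2000 regions, depth 200,
dispersion 0.02): KS distance of Wald p values from uniform ~0.02-0.05,
tail frequency P(p < 0.001) ~ 0.001, zero PRE/NRE calls across 20 null
screens at FDR 0.01.

## Regulatory-SNP (allelic imbalance) test

Each replicate library's allele counts are rescaled so library totals
are equal (depth normalization; a per-SNP-coverage mode is available as
`mode="snp_coverage"`), summed over replicates within condition, and
SNPs with any of the four pooled values below 10 are dropped. The effect
size is the ratio of allele ratios, output over input, alt over ref
(reciprocal also reported). Pooled normalized counts are rounded
half-to-even to form the integer 2x2 table (condition x allele) for the
two-sided Fisher exact test; BH across tested SNPs flags regulatory SNPs
at adjusted p < 0.1, each annotated with its host region's class.

The package's exact-test odds ratio is everywhere the conditional MLE:
the odds psi maximizing the Fisher noncentral hypergeometric likelihood
given the margins, found by solving `E_psi[X] = x` with Brent's method
on log psi; the 95% CI inverts the exact conditional tails at alpha/2
each (the interval classical implementations report). Boundary tables
give OR 0 or infinity; a zero margin gives p = 1 with OR undefined.

## Enrichment and motif deltas

Peak overlap is point-in-interval on the SNP position over merged,
sorted peak intervals (verified against naive membership). Enrichment
tables are class x in-peak counts passed to the conditional-MLE Fisher
test. PWM scores use log2(p/background) with pseudocount 0.01 added
before normalization (background uniform by default); an allele's score
is the maximum over all motif windows covering the SNP, on both strands
by default. Note a strand subtlety: for palindromic contexts or very
short motifs, the reverse strand can score the opposite allele's
complement, so single-strand scoring is available (`both_strands=False`).
A SNP is motif-disrupting when max |delta| over motifs >= 3 (log2
scale); optional ChIP-seq peak support per motif (a factor-to-track
mapping) gates which SNP x motif pairs count, default off so the stage
runs without external data.

## Coverage simulation

For pool sizes i, the simulator samples i individuals without
replacement (five repeats by default, mean and sd reported) and counts
SNPs whose sampled dosages include both alleles; the denominator is the
designed panel size, not the polymorphic count. The closed form
`1 - (1-f)^(2i) - f^(2i)` assumes HWE sampling with replacement and is
used as the validation oracle for pools much larger than i.

## Two-step eQTL

Both regression steps include intercepts (the compact model equations
omit them, but residualization without an intercept is almost surely
unintended); genotype is coded additively 0/1/2, covariates are left
unstandardized, and missing rows are dropped listwise with counts
reported. When genotype is orthogonal in sample to (1, C, M) the
two-step estimate equals the joint-OLS genotype coefficient, which the
tests assert to 1e-8. A one-tailed group-mean contrast of residuals
(carriers vs non-carriers, Welch) is available for candidate-directional
hypotheses.

## Synthetic data: what it emulates, what it does not

The generator reproduces the structure the statistics consume: a panel
of tag+linked SNPs with uniform MAF on [0.05, 0.5]; a diploid pool under
HWE with independent SNPs (no LD — irrelevant to the statistics under
test); per-region per-replicate counts in which the input mean is the
region's fragment budget (default lambda = 200, matching a deeply
covered screen), the output mean multiplies in the planted activity and,
for alt-allele fragments, the planted allelic effect; and fragment
records (length ~N(465, 40) truncated to [400, 600], covering their SNP)
materialized consistently with the counts. Noise is NB at the region
total (default dispersion 0.02, configurable and echoed in the output
metadata) with a binomial allele split of the total: a region's
fragments share transfection/PCR noise, so allele-ratio noise is
sampling noise within the fragment pool. Drawing the two alleles as
independent NB variables instead would plant allele-ratio
overdispersion that no exact test tolerates and that the tight observed
replicate correlation of real screens argues against.

Planted activities are log-uniform over [0.5, 16] split into PRE (>1)
and NRE (<1) regions at configurable exact fractions;
`fixed_activity_folds` plants exact folds for power studies. Allelic
effects default to log-uniform folds in [1.5, 3], inverted to the
reciprocal with probability 0.5. Panel SNPs are spaced 1000 bp apart so
a generated fragment covers exactly one SNP; multi-SNP counting is
exercised by handwritten fixtures. Not emulated: sequencing error, PCR
duplicates, capture-efficiency bias, LD, and real genomic sequence
context — so passing tests demonstrate statistical correctness and
calibration under the stated noise model, not robustness to alignment
or library artifacts.

Annotation peaks are planted per SNP: inactive-region SNPs fall in a
peak with the baseline rate, PRE/NRE SNPs with odds scaled by the target
odds ratio; peak intervals are random 40-800-bp windows covering the
SNP.

## Problem sizes used in the test suite

Simulation-backed tests run at 200-2000 regions with 2 replicates per
library: null-calibration and FDR checks on 20 screens of 2000 regions;
sign-recovery at lambda = 500, dispersion 0.01 (the concrete
recovery-example conditions; at lambda = 200, dispersion 0.02 the
delta-method sd of log2FC is ~0.23, so a 90% sign-recovery bound for
fold-0.5 elements is not attainable by any estimator at FDR 0.01);
allelic recovery at lambda = 500 with fold-2 effects; enrichment
round-trips on 6500-SNP panels over 50 peak draws. The exact test is
verified against exhaustive hypergeometric enumeration on every 2x2
table with total <= 40.

## Known limitations

Single-factor designs only (input vs output, shared design across
regions); no outlier-count replacement; the Wald test is asymptotic and
slightly anticonservative near p ~ 0.01 at 2+2 replicates (measured
factor ~1.1-1.3 at the 0.01 tail, controlled after BH at the FDR
thresholds used); the allelic exact test treats pooled rounded counts as
binomial sampling, which understates uncertainty if real libraries carry
allele-level overdispersion beyond the shared region noise; indels and
multi-allelic sites are out of scope.
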
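# Methods

## Per-SNP statistics

**Fst.** The two-population Weir & Cockerham (1984) estimator is computed
per SNP from diploid genotype counts; observed heterozygosity enters the
within-individual component c, and `theta = a/(a+b+c)`. The raw estimate
is kept signed (it can be negative in balanced samples); SNPs monomorphic
in both populations yield an absent value (NaN), not zero. Missing
genotype calls are handled pairwise-complete: a sample is excluded at a
SNP when either of its two calls is missing, and SNPs with fewer than two
usable diploids in a population are absent.

**PBS.** Pairwise Fst values are clamped to [0, 1−10⁻⁶] before the log
transform `T = −ln(1−Fst)`; the upper clamp keeps branch lengths finite
at fixed differences, the lower clamp zeroes the (noise-driven) negative
estimates only inside PBS, so exported Fst tables stay comparable to
standard tools. `PBS_A = (T_AB + T_AC − T_BC)/2`.

**nSL.** For a focal SNP, haplotypes are split into ancestral- and
derived-allele carriers using the VCF `AA` annotation (upper-cased; SNPs
whose AA matches neither allele are skipped and counted). For each
haplotype pair within a class the identity tract is the number of
consecutive SNPs (index space, focal included) over which the pair
agrees, truncated at the data edge and at `max_extend = 100` sites each
side (configurable; mirrors common scan-tool practice). `raw =
ln(SL_A/SL_D)`; strongly negative scores mean long homozygosity around
the derived allele. Raw scores are standardized within equal-width
derived-allele-frequency bins (default 20; the synthetic power studies
use 10 because they score ~200 focal sites, and 20 bins would leave bins
with fewer than the 2 scores standardization needs). The outlier rule
|z| ≥ 2 is applied to the standardized score: raw values near ±2 would be
far outside the observed raw distribution, so the threshold only makes
sense on the normalized scale. Haplotype statistics require complete
columns; variants with missing calls are dropped first (frequency and
Fst statistics keep them).

## Sweep filter cascade

LD pruning is greedy p-ranked clumping: SNPs are visited by ascending
GWAS p (ties by position) and kept unless r² with an already-kept SNP
within 500 kb exceeds 0.1. This makes the extraction deterministic.
PBS outliers are SNPs at or above the per-triplet empirical 99th
percentile (linear-interpolation quantile; ties at the threshold
retained), intersected across the three triplets; the association filter
is strict (P < 5×10⁻³) while the nSL locus rule is inclusive (|z| ≥ 2),
matching the asymmetry of the two conventions. A locus passes on the
score of its top SNP only (minimum GWAS p; ties by position). Gene-set
enrichment is a standard hypergeometric upper tail with BH correction —
a deliberate replacement for hosted annotation services, so corrected
p-values are not comparable to any particular service release.

## PBS selection index

Genes are binned by SNP count at window 11. The remainder rule — a
remainder of ≥ 6 SNPs forms its own bin, < 6 merges into the preceding
bin — keeps every bin size in [6, 16] (single-bin genes can be smaller),
so one cached permutation null per size serves all bins of that size.
A bin's index is `(1 + #{null means ≥ observed})/(1 + n_perm)` with null
means drawn as uniform same-size SNP sets (distinct indices) from the
genome-wide PBS pool; the add-one correction keeps indices strictly
positive so FDR adjustment is well defined. Each size's RNG stream is
derived from (seed, size), making any subset of bins reproduce the full
run exactly.

The per-gene index is the mean of the gene's **raw** bin indices, with
the mean of BH-adjusted bin indices reported alongside (`q_index`). The
raw mean is the calibrated choice: under the null, raw indices are
uniform and the fraction of genes below the 0.01 threshold sits at the
nominal level (the measured fraction is slightly below 0.01 because
multi-bin genes need several small uniforms at once), whereas a mean of
BH-adjusted values collapses to ~1 for every gene when nothing is
selected and the genome-wide significant fraction would be ~0 rather
than ~1%. Significance is strict (< 0.01).

Term-level testing uses a pooled-variance one-sided two-sample z test of
the significant-gene proportion in the term versus its complement (no
continuity correction). Terms are first intersected with the scored-gene
universe, filtered at the median in-universe gene count (ties retained),
then pruned by cutting a Ward tree over 1 − Jaccard gene-set distances at
height 0.5, keeping the largest term per cluster (ties: smallest id).
The Jaccard distance replaces semantic-similarity measures that require
the ontology graph; a user-supplied distance matrix can restore any
preferred measure.

## Gene–environment Bayes factor

Population allele frequencies are standardized per SNP,
`y_l = (p_l − p̄)/sqrt(p̄(1−p̄))` with the unweighted across-population
mean; fixed SNPs are dropped. Ω is the empirical covariance of
standardized control SNPs (at least 10·L required), shrunk toward its
diagonal (λ = 0.05) to guarantee positive definiteness. The Bayes factor
is the mean over an equally spaced, symmetric β grid on [−0.3, 0.3]
(201 points) of the Gaussian likelihood `N(y; β·env, Ω)` divided by the
likelihood at β = 0; environments are z-standardized across populations
and latitude enters as absolute degrees by default (the sunlight-exposure
reading — distance from the equator, not hemisphere, is what matters).
This grid-averaged Gaussian approximation is deterministic; it does not
reproduce the magnitudes of MCMC-based Bayes factors, and only rank
behaviour (planted signal above null) is asserted anywhere. The grid's
symmetry about zero makes the factor invariant to which allele is
counted. Both the bound and the grid size are configurable; 0.3 spans
effects well past what drift-scale covariance can absorb, and 201 points
keeps the grid average within 10⁻⁶ of an independent quadrature.

## Mendelian randomization

Harmonization aligns outcome records to the exposure effect allele,
resolving strand complements, sign-flipping swapped alleles, and dropping
palindromic (A/T, C/G) SNPs, whose strand cannot be resolved without
frequency information. IVW is the fixed-effect inverse-variance-weighted
slope through the origin with `w = se_Y⁻²` (a multiplicative
random-effects variant is not the default because the synthetic truth is
fixed-effect). MR-Egger orients exposure betas non-negative before the
weighted fit; intercept and slope inference uses the t distribution with
n−2 df. Leave-one-out flags exclusions that flip the estimate's sign or
leave the full-set 95% interval.

## Synthetic data: what it emulates, and what it does not

* **Allele-frequency divergence** follows the Balding–Nichols model:
  population frequencies drawn Beta(p(1−F)/F, (1−p)(1−F)/F) around an
  ancestral p, so mean and variance (F·p(1−p)) are known exactly and the
  generator itself is testable. Defaults: F = 0.05 (continental-scale
  drift), 100 diploids per population (1KGP-like sample sizes),
  ancestral frequencies uniform on (0.05, 0.95). Directional selection
  is a fixed frequency shift in one population, clipped to [0.01, 0.99].
* **Sweep haplotypes** come from a founder-copying mosaic (20 founders,
  per-site template-switch probability 0.1) with a core haplotype
  inserted across 101 of 201 sites at the chosen frequency, perturbed by
  private mutations (rate 0.01/site), the focal site's derived allele
  carried by exactly the core copies. This gives direct control of the
  tract-length contrast nSL measures without a full coalescent
  simulation; it has no recombination map, demography or time axis.
* **Gene architecture**: SNP counts per gene are 1 + NegBin(r = 6,
  p = 1/3) — a right-skewed distribution with mode 11 and mean 13,
  matching the skew of GWAS gene annotations; terms draw genes at
  random, with one planted term whose genes carry the selection signal.
* **Environment-correlated frequencies**: standardized frequency vectors
  drawn MVN(β·env, Ω) and mapped back through the standardization, with
  drift-scale Ω = 0.01·I in the study designs.
* **MR instruments**: `β_Y = α + β·β_X + ε`, reported standard errors
  equal to the generating scales, with configurable fractions of
  allele-swapped and palindromic rows to exercise harmonization.

Passing these designs shows the estimators and filters are correct and
calibrated under their own assumptions; it says nothing about LD between
causal and tag SNPs, ascertainment of GWAS panels, real demography, or
annotation quality — all of which affect real-data runs.

## Study designs and problem sizes

The acceptance experiments (tests and `scripts/acceptance.py`) use:
null calibration and size-bias at 4,000 genes × 5,000 permutations × 10
seeds; polygenic power with the planted term's genes spiked by +2 pooled
SD of PBS (50 replicates in the test suite, 20 in the script); the nSL
filter with 10 sweep loci (core frequency U(0.25, 0.85)) against 200
neutral loci of 200 haplotypes each; the PBS cascade with 20 SNPs
shifted +0.5 among 4,000 (the planted set is restricted to alleles with
frequency headroom — an allele already near fixation everywhere cannot
register a branch-specific shift); MR coverage and Egger size at 500
replicates of 50 instruments; Bayes-factor separation at 10 populations,
500 + 500 SNPs, β = 0.25, 20 replicates. Sweep scores are kept a small
minority of every frequency bin: normalization statistics are only
meaningful against a predominantly neutral background.

## Numerical notes and degenerate inputs

* Quantiles use linear interpolation; ties at thresholds are retained.
* Permutation draws reject and redraw rows with duplicate indices
  (collision probability ~k²/2m, negligible at the pool sizes used).
* Bin standardization uses the population (ddof = 0) standard deviation;
  bins with < 2 scores or zero variance yield absent z-scores.
* The proportion test returns z = 0, p = 0.5 when the pooled variance is
  zero (all or no genes significant in both groups).
* OLS/WLS fits go through statsmodels; adjusted R² may be negative.
* All generators and permutation machinery are bit-reproducible given
  (config, seed); per-stage seeds derive from one global seed.

## Known limitations

Real-data headline counts from the original study design (SNP/gene/term
tallies, service-corrected enrichment p-values, MCMC Bayes-factor
magnitudes) depend on external GWAS releases, annotation-service
versions and samplers, and are out of scope. iHS and XP-EHH (genetic-map
based), multi-population Fst beyond pairs, weighted-median/mode MR
estimators, and GO-graph semantic similarity are not implemented.
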
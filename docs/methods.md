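# Methods

This note records the models, conventions and numerical choices behind
`admixqtl`, and what the synthetic test-bed does and does not establish.

## Genotype model and containers

Genotypes are dense sample × SNP alt-allele dosage matrices (0/1/2, NaN for
missing), the natural representation for SNP-array data. Coordinates are
1-based and inclusive (VCF convention). Dosages always count the alt allele
as written; there is no strand flipping — the package assumes a single
panel of record, as with one genotyping array shared by study and
reference. Sample alignment across files is by exact string id,
intersect-with-warning.

## EIGENSTRAT normalization

Per SNP: center at the mean called dosage, scale by `sqrt(p̂(1−p̂))` with
the posterior frequency `p̂ = (1+Σg)/(2+2n_called)`. The posterior estimate
never reaches 0 or 1, so monomorphic SNPs cannot divide by zero. Missing
entries become 0 after centering and therefore contribute nothing to any
PC. All-missing columns are dropped with a log line.

## PC spaces, projection and its bias

`fit_pca` takes the top right singular vectors of the normalized matrix;
eigenvalues are squared singular values over (n−1); the panel's own
coordinates are `U S = X_norm V`, so projecting the panel into its own
space reproduces them exactly (machine precision; the test bound is 1e-6).

Projection of a study cohort uses the *reference's* per-SNP center and
frequency, then multiplies by the loadings. No shrinkage correction is
applied: projected samples are known to be biased slightly toward the
origin when the panel is small relative to the number of SNPs. For the
ancestry *fraction* this bias largely cancels because both the sample and
the two population centroids live in the same space; the parameter-recovery
tests (correlation ≥ 0.99 with generator truth at 200 samples × 5,000 SNPs)
quantify what remains. SNPs sharing an id but disagreeing on (ref, alt)
alleles are excluded from projection with a logged count.

`ancestry_fraction` is the scalar projection of (x − centroid_A) onto the
A→B axis over its length, clamped to [0,1], computed on the leading 2
dimensions by default. It is invariant under any orthogonal rotation
applied jointly to coordinates and centroids.

## LD thinning

Greedy positional scan per chromosome, first-kept-wins: a SNP is dropped
when its squared dosage correlation with any retained SNP within the window
(default 1 Mb) exceeds `r2_max`. The default `r2_max = 0.2` is the common
pruning threshold for PCA input; under independent simulated SNPs the null
r² is ~1/n, so ≥95% of SNPs survive at cohort sizes of a few hundred.
Monomorphic SNPs are dropped up front (undefined correlation); missing
entries are mean-imputed for the correlation only. The rule is
deterministic and order-stable.

## Tracy-Widom dimension count

For the i-th leading eigenvalue the remaining spectrum is treated as a
fresh dataset of m−i dimensions (m = number of nonzero eigenvalues, which
absorbs the rank loss from centering). The effective marker count is the
moment estimate `n' = (m+1)S₁²/((m−1)S₂ − S₁²)`, *capped at the actual
marker count*: the moment estimate is designed to discount correlated
markers and overshoots the truth by several percent for independent
markers, which inflates the statistic by roughly +1.7σ on a 200×2000 iid
null and would mis-calibrate the test. Eigenvalues are normalized to
`l = m λ / S₁` and standardized with the usual center and scale; spectra
flatter than the null (negative moment denominator) are treated as not
significant. The decision rule counts leading consecutive statistics above
the 5% critical value 0.9794; the looser "statistic > 0" convention is
available as `rule="positive"`.

## Trait preprocessing

Quantile normalization across the two collection batches maps each batch's
per-trait values (mid-ranks at plotting positions (r−½)/n_b) onto the
pooled empirical quantiles, so the batch distributions coincide exactly for
equal batch sizes while within-batch orderings are preserved. A singleton
batch maps to the pooled median.

Covariate/PC adjustment fits, per trait, a Huber M-estimated linear model
(tuning constant 1.345, ≤50 iterations, coefficient tolerance 1e-8) of
trait on intercept + age + sex + PC1..PCk. Residuals are re-centered to
mean zero — a location shift is irrelevant to the rank test but makes the
residual container's mean-zero invariant exact. The "unadjusted" arm is
k = 0 and still removes age and sex. Rank-deficient design columns are
dropped with a warning.

## Kruskal-Wallis scan

Mid-rank statistic with the standard tie correction
`1 − Σ(t³−t)/(N³−N)` (the bare formula is conservative under ties;
`tie_correction=False` restores it). p is the upper χ² tail with g−1
degrees of freedom, g = number of non-empty genotype groups (minimum group
size 1; empty groups reduce g). All-tied values give (K=0, p=1); pairs with
fewer than two groups are omitted with a counter. The scan is vectorized:
for a fixed trait the ranks are SNP-independent, so all group rank sums are
three indicator-matrix products; with missing genotypes the scan falls back
to per-pair tests. The χ² approximation is anti-conservative for very small
groups; at N ≤ 8 it stays within a factor ~3 of the exact permutation
p-value (tested by full enumeration).

The cis boundary is inclusive: |pos_SNP − pos_gene| ≤ 1,000,000 bp on the
same chromosome. Gene position is one representative integer per trait
(the generator uses a TSS stand-in placed within the causal SNP's window).
All trait-SNP pairs are tested and partitioned afterwards.

Effect size is the robust-fit r² of trait on additive dosage,
`1 − Σw e²/Σw (y−ȳ_w)²` with the converged Huber weights; undefined
(reported absent) when the weighted variance vanishes.

## Permutation FDR

One random permutation of the sample axis per replicate, applied to the
whole residual matrix, preserves trait-trait correlation exactly. Candidate
thresholds are the sorted observed p-values; per class (cis/trans),

    FDR̂(t) = [(1 + Σ_b #{null_b ≤ t}) / (B + 1)] / #{obs ≤ t},

with B = 10 permutations by default and π₀ = 1. Counting the observed scan
as one extra null set is the standard conservative convention for
permutation tests; without it a single observed p-value smaller than every
null p-value (probability ≈ 2/(B+1) across two classes by exchangeability,
regardless of the data) already qualifies at a 10% level, and the estimator
over-calls under a global null. Even with the conservative convention,
under a global null FDR equals family-wise error, so each class still
rejects with probability up to ≈ 1/(B+1) ≈ 9% — zero discoveries on null
data is expected in about 10/11 of runs per class, not always. Discovery
counts and cutoffs are non-decreasing in the FDR level by construction;
classes with no qualifying threshold report no cutoff and zero discoveries.

The expected false count at a level is `int(level × n_discoveries)`, and
the relative power of two analyses at a common FDR reduces to the ratio of
their discovery counts.

## Pseudo-cis null

Per run, each trait receives a uniformly random window (default 2 Mbp)
fully inside a random chromosome, chromosomes weighted by the number of
placeable windows; windows overlapping the trait's true cis region are
redrawn (toggleable) so the count measures background only. A trait scores
when any SNP in its window reaches the cis p-cutoff from the true analysis
at the same FDR level. A deterministic cross-check enumerates window start
positions on a 100-kb grid and averages the hit indicator — the Monte-Carlo
mean agrees within sampling error.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume: a
drifted multi-population panel with tight clusters, a continuously admixed
cohort (two-way cohorts form a line on self-eigen PCs, three-way a V/Y),
ancestry-correlated allele frequencies and expression shifts, age/sex
covariates, two collection batches with an optional location/scale
distortion, and planted cis effects with known truth. Defaults describe the
small-admixed-cohort regime: 60 study samples, two-way Dirichlet(1,1)
admixture, F_ST = 0.2 per population (continental-scale drift), 2,000
independent SNPs over 5 chromosomes × 50 Mbp, 100 traits with 30 cis
effects sized to r² ≈ 0.5 at unit noise (`beta_for_r2` gives the closed
form), ancestry expression shifts of 1 trait-SD scale, age 0.02 SD/year and
sex 0.5 SD. The ancestry effect enters through the continuous dose q₁, not
discrete labels. Seeds: one master seed; the panel, cohort and expression
sub-generators use fixed documented offsets (+1, +2, +3), and identical
(config, seed) is bit-reproducible.

Deliberately absent: linkage disequilibrium (an optional block-copy mode
exists only to exercise the pruner), recombination maps, realistic
population frequencies, relatedness, and genotyping error. Consequences
worth knowing:

* Passing tests show the *methods* behave as specified under the model, not
  that real cohorts are as clean; real data adds LD and fine structure.
* With two-way admixture only PC1 carries ancestry. Adjusting a 2nd or 3rd
  PC costs a single random degree of freedom — an expected power decrement
  near zero. The headline trade-off (unadjusted vs any adjustment) is large
  and reproduces in every seed; the strict monotone chain across 1, 2 and 3
  adjusted PCs is at the mercy of FDR-count noise here, whereas on real
  admixed data higher PCs still absorb structure and the chain is cleaner.
  The power-ordering check therefore uses several hundred traits (the
  many-phenotype design that makes empirical power comparison meaningful)
  and still reports a fraction, not a certainty.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
each property has clear signal: panels of 100 per population; cohorts of
60-200 samples (1,500 only for the PC-geometry check, where the PC2 noise
eigenvalue scales as m/n and must sit well below the ancestry eigenvalue);
300-5,000 SNPs; 40-300 traits; 10 permutations; 200-300 pseudo-cis runs.
The pseudo-cis comparison uses 200 runs rather than 1,000; its Monte-Carlo
error enters the assertions explicitly.

## Known limitations

* The projection applies no shrinkage correction (documented bias above).
* The FDR estimator assigns class-level cutoffs, not per-test q-values.
* No kinship or mixed-model correction; no genomic control.
* The χ² tail of the rank test is approximate for very small genotype
  groups; exact enumeration is only used in tests.
* Probabilistic/imputed genotypes and PLINK binary formats are out of
  scope.
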
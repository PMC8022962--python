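# Methods

`locusfdr` implements and evaluates multiple-testing procedures for
common-variant GWAS summary statistics, where discoveries are counted in
units of *loci* — clusters of nearby variants correlated through linkage
disequilibrium (LD) — rather than individual variants.

## Statistical model

Per variant *j*, an additive model for a quantitative trait *Y*:

    Y = X'beta + G_j * theta_j + eps_j,    eps_j ~ N(0, sigma_j^2),

with dosage G_j in {0,1,2} and, throughout this package, an
inverse-normalized (unit-variance) trait and no covariates beyond the
intercept.  Each variant is tested for H0: theta_j = 0 by simple linear
regression; the scan reports the effect estimate (BETA), its standard
error (SE), Z = BETA/SE, and a two-sided P-value from the t distribution
with n-2 degrees of freedom.  When only Z, the effect-allele frequency p
and the sample size n are available, the effect scale is recovered as

    SE = 1 / sqrt(2 p (1-p) (n + Z^2)),    BETA = Z * SE,

which is exact for a variance-standardized trait.  This standardization
assumption is load-bearing: on a raw trait scale the reconstruction is off
by the trait SD.

## Procedures

- **Fixed P-value thresholds** (FWER-style control): reject P < alpha_p,
  with strict inequality ("P < 5e-8").  Bonferroni rejects
  P <= alpha/m and optionally substitutes an effective number of
  independent tests m' <= m; alpha = 0.05 over one million effective
  common-variant tests reproduces the genome-wide 5e-8 convention.
- **Adapted Benjamini–Hochberg / Benjamini–Yekutieli** (FDR control):
  because FDR control does not transfer to a subset of rejections, all m
  tested variants are first LD-clumped (r^2 > 0.1, 1 Mb window) into
  m* < m loci and the step-up runs on the m* lead-variant P-values:
  k = max{k : p(k) <= k*alpha/(m*c)}, with c = 1 for BH and
  c = sum_{i<=m*} 1/i for BY (valid under arbitrary dependence, and
  markedly conservative).
- **Bayesian FDR via the approximate Bayes factor**: with sampling
  variance V = SE^2, a N(0, W) effect prior and r = W/(V+W),

      ABF = (1-r)^{-1/2} exp(-Z^2 r / 2),
      BFDP = ABF*PO / (ABF*PO + 1),   PO = (1-pi1)/pi1.

  Note the convention ABF = P(data|H0)/P(data|H1): small values favor
  association.  pi1 is estimated as the proportion of tested variants
  with P < 5e-8 (a floor of 1/(10m) prevents infinite prior odds in
  underpowered studies; a loci-count/1e6 alternative estimator is
  provided).  The Bayesian FDR step-up rejects the k smallest lead-variant
  BFDPs where k is the largest index at which their running mean is
  <= alpha.  W defaults to 0.04 (prior SD 0.2 trait-SD per allele), a
  conventional choice for quantitative traits; it is per-study
  configurable.
- **Multi-trait testing**: metaMANOVA t = z' Omega^{-1} z ~ chi^2_L under
  the joint null, with Omega the trait correlation matrix estimated as the
  Pearson correlation of Z columns over variants with max|Z| < 2
  (truncation attenuates the estimate slightly — a property of this
  standard plug-in, traded for robustness to signal; a known-null mask
  gives an unbiased estimate).  The multivariate ABF is the density ratio
  N_L(z; 0, Omega) / N_L(z; 0, Omega + W I) — an independent
  standardized-effect prior with common variance W, chosen because it
  reduces exactly to the univariate ABF at L = 1 and factorizes over
  traits when Omega is diagonal.  Parallel univariate testing divides the
  P threshold by the trait count L.

## Clumping

Greedy and P-ordered: the unassigned variant with the smallest P becomes a
lead; every unassigned same-chromosome variant within the window (lead to
member, inclusive) with r^2 above the threshold joins its locus; repeat.
r^2 is the squared Pearson correlation of in-sample dosages.  P ties are
broken by (chromosome, position, id) so the partition is deterministic.
Distance-only clumping is the same loop without the LD condition.
Cross-chromosome LD never merges loci.

## Empirical-FDR evaluation

The largest available study of the trait serves as the operational truth.
A test locus is a true positive when its lead variant has r^2 > 0.80 with
*any* truth variant at P < 5e-8 (strict), r^2 > 0.60 at P < 5e-7
(relaxed), or lies within +/-50 kb of such a variant (distance mode);
otherwise it is a false positive.  Matching consults any qualifying truth
variant, not only truth leads, and for the LD modes only variants within
1 Mb of the lead are examined (high LD beyond that distance is negligible
for common variants).  eFDR = V/(V+S), defined as 0 when nothing is
rejected.  Two clumping regimes mirror the two procedure families:
fixed-threshold procedures clump only their significant variants, while
BH/BY/BFDP clump all tested variants and reject whole loci via their
leads.  Report tables print percentages to two significant figures
(half-up), the precision used in consortium-style summaries.

## Synthetic data

The generator reproduces the statistical structure of a consortium GWAS
at desk scale, with no external downloads:

- **Genotypes**: independent blocks; within a block each of the 2n
  haplotypes is a latent AR(1) Gaussian (parameter rho, default 0.95)
  thresholded at the quantile of a target MAF drawn uniformly from
  (0.05, 0.5); the dosage is the haplotype sum.  This yields decaying
  within-block LD (adjacent dosage r^2 typically 0.5-0.75 at rho = 0.95 —
  dichotomization attenuates the latent correlation) and exactly zero
  between-block LD.  Blocks start 2 Mb apart and span < 200 kb, so they
  always clump into distinct loci.  An AR-threshold model was chosen over
  coalescent simulation: it is fast, directly parameterizable, and
  sufficient for procedures that consume only P-values and r^2.
- **Effects**: one causal variant per chosen block ("well-separated truth
  loci"); default law theta = s|N(0,1)| with random sign, s calibrated so
  the explained variance sum var(g_j) theta_j^2 equals the target h2
  (default 0.2 over 30 causal blocks); an explicit effect list is
  accepted.  Residual noise N(0, 1-h2) keeps the trait at unit variance;
  an optional rank-based inverse-normal transform is available.
  Multi-trait generation adds row-wise Gaussian residuals with a
  configurable residual correlation and unit total variances.
- **Paired studies**: one genotype pool; the test study scans a fresh
  phenotype on n_test individuals.  The truth study (default
  n_truth = 100,000 against n_test = 20,000) is emulated on the same pool
  with its residual SD shrunk by sqrt(n_test/n_truth): both the expected
  value and the sampling noise of the truth Z statistics then match a
  study of n_truth individuals (only allele-frequency resampling noise is
  absent, consistent with the fixed-genotype replicate design).  Setting
  `truth_mode="genotyped"` instead draws and scans the full n_truth pool.
- **P-values** come from the t distribution (exact at small n,
  indistinguishable from normal at GWAS n) and are floored at 1e-300,
  with a LOG10P side column carrying the unclipped magnitude.

What the generator does **not** emulate: population structure and
relatedness, imputation error, cross-block LD, allele-frequency
differences between studies, binary traits, and genome-scale test counts
(see "Desk-scale caveats").  Passing tests therefore demonstrate the
procedures' behavior under clean polygenic architecture, not robustness
to those artifacts.

## Replicate studies

Genotypes and the causal model are generated once per configuration and
reused; each replicate draws new phenotypes (test and truth
independently), scans, applies every configured procedure, and labels
rejected loci.  By default the truth set is rebuilt each replicate from
the truth scan — the same evaluation the empirical design uses; labeling
directly against the causal variants is available
(`truth_source="causal"`) and is substantially stricter, because a
detected locus led by a close LD partner of the causal variant (dosage
r^2 below 0.8) then counts as false.  eFDR is aggregated as the mean of
per-replicate ratios (replicates with R = 0 contribute 0), matching
FDR = E[Q]; the ratio of mean counts is reported alongside.  Monte-Carlo
SEs are sample SD / sqrt(reps).  Child seeds derive from the master seed
by replicate index, so any replicate is reproducible in isolation.
Default reps = 1000; the desk-scale preset uses 200 (SEs widen ~2.2x).

## Problem sizes used by the test suite

The packaged tests run the full pipeline at M = 20,000 variants in 200
blocks, 30 causal blocks, n_test = 20,000 (and 5,000 for the sample-size
comparison) against n_truth = 100,000, 200 replicates — a deliberate
~100x reduction from the 2.1M-variant consortium scale.  Unit and
property tests use much smaller panels.

## Desk-scale caveats

Two consequences of shrinking the variant count deserve emphasis.

1. **The genome-noise floor nearly vanishes.**  With ~10^6 effective
   tests, a real GWAS accumulates ~0.5 false loci per study between
   P = 5e-8 and 5e-7 regardless of sample size; at M = 20,000 this floor
   is ~0.005.  The false positives that remain at desk scale are
   *winner's-curse halo loci* — weak LD partners of causal variants whose
   test statistic was selected upward and which the truth study cannot
   certify — and their number grows with test-study power.  The
   empirical pattern "the percent-true of additional loci rises with
   sample size", which in full-scale data is driven by true gains
   outgrowing the constant noise floor, is therefore not expected to
   reproduce at desk scale, and the corresponding packaged check
   documents this directly.
2. **Adapted BH at loose levels is anti-conservative here.**  With only
   m* ~ 2,800 loci, the BH cut at alpha = 0.05 falls near z ~ 3.1, deep
   in the halo band, and the measured eFDR against a 5x-powered truth
   scan is far above alpha.  This is a property of the locus count and
   the truth-certification gap, not of the step-up implementation, whose
   calibration is verified separately on independent hypotheses (where
   BH holds its level and BY is uniformly more conservative, as theory
   requires).

## Numerical choices

- r^2 and scans use float32 BLAS kernels with float64 reductions; r^2 is
  accurate to ~1e-4, ample for thresholding at 0.1/0.6/0.8, and scan Z
  statistics to ~1e-4 relative.
- Step-up comparisons use "<=" (printed inequalities); fixed thresholds
  use strict "<".
- Constant dosage columns: scans skip them with a log message; LD queries
  raise, since r^2 is undefined.
- Degenerate inputs: empty clumping input yields an empty locus set;
  an empty truth set labels every locus false positive with a warning;
  harmonization raises on an empty intersection.

## Known limitations

- In-sample LD only; no external reference panel support.
- No conditional/stepwise analysis within loci; leads are greedy.
- The pi1 plug-in is conservative by construction and floored; no
  local-FDR or q-value machinery.
- Allele harmonization matches ids verbatim and resolves only
  effect/other swaps; strand flips and indels are dropped, and no
  genome-build liftover is attempted.
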
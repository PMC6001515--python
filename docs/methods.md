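# Methods

## The model

For a set of M SNPs, a polygenic risk score combines a person's counted
risk-allele dosages g = (g_1, …, g_M), g_i ∈ {0, 1, 2}, with per-SNP
log odds ratios β estimated in an independent discovery sample:

    PRS = Σ_i β_i g_i = βᵀ g.

When SNPs are in linkage disequilibrium (LD), correlated markers enter
this sum several times over: written in the eigenbasis of the M×M SNP
correlation matrix C = Σ_k λ_k x_k x_kᵀ (λ_k ≥ 0, Σ_k λ_k = tr C = M,
x_k orthonormal), the spectral component of g along axis k contributes
variance proportional to λ_k, so high-LD directions (λ_k ≫ 1) dominate.
The LD-adjusted score removes that anisotropy by rescaling each
principal-axis coordinate with the inverse square root of its
eigenvalue, stabilised by a ridge term λ₀ against near-zero eigenvalues:

    g̃ = √(1+λ₀) (C + λ₀ I)^{-1/2} g,      score = βᵀ g̃.

The correlation matrix (not the covariance matrix) is used so that only
LD is adjusted, not single-marker variance; a covariance mode is
available as an alternative. The √(1+λ₀) factor makes the transform the
exact identity when C = I, so with uncorrelated markers the adjusted
score coincides with the plain PRS. With λ₀ = 0 the transform is the
pseudoinverse square root: axes with λ_k = 0 (no variance) are omitted.
We call λ_k "zero" when λ_k < 1e-10·M; this tolerance is our choice —
it cleanly separates round-off from genuine rank deficiency at any set
size we handle.

The set-level test regresses case/control status on the per-person
score by logistic regression (β are log odds ratios, so a logistic link
is the consistent choice); the Wald z of the score coefficient gives a
two-sided self-contained p-value, and covariates enter the regression
directly. If the Wald fit degenerates (non-convergence, separation) a
likelihood-ratio test against the score-free model is substituted and
logged. Quantitative phenotypes use ordinary least squares with a
t-test. Because the score is the only genetic predictor, adding any
constant to it moves only the intercept: location shifts of the score
(e.g. from centering g before adjustment) cannot change the p-value.

The comparator implemented alongside is the PCA set test: principal
components of the centered set genotype matrix, components retained
largest-first up to 99.9% cumulative explained variance (configurable;
zero-variance directions never count), linear regression of phenotype
on the retained components, overall F-test.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| λ₀ (ridge) | 1/N | added to all eigenvalues before inversion; N = test-set individuals. Keeps near-singular LD finite while leaving well-conditioned spectra essentially untouched (factors → 1 as λ₀ grows). |
| MAF filter | 0.01 | SNPs with folded minor-allele frequency strictly below threshold are dropped (keep maf ≥ t, the PLINK convention). |
| variance_kept | 0.999 | PCA comparator pruning rule. |
| anneal gap | 250,000 bp | significant genes on one chromosome closer than this (strictly) merge transitively into one locus. |
| genomic-control λ | none | when supplied (≥ 1), per-SNP χ² is divided by λ: SE × √λ, p recomputed, β untouched. |

Allele conventions: the counted allele is the .bim A1 allele; summary
files declare their effect allele explicitly and are never inferred from
frequency. Harmonization inverts β when the summary alleles are the
test pair reversed, removes strand-ambiguous A/T and C/G SNPs, and
removes unmatched allele pairs with a logged reason; the reconciliation
counts are always reported. Missing genotypes are imputed as 2×MAF with
MAF computed from the test set's non-missing calls and folded to
[0, 0.5]; note that when the counted allele is the major allele this is
not the column mean — it follows the stated 2×MAF rule, which assumes
the minor allele is counted. Gene boundaries are inclusive on both ends
(1-based .bim coordinates) and a SNP inside several overlapping genes
joins all of them; both choices are configurable because the underlying
conventions are genuinely open.

## Simulation harness

Scenario A ("one LD block") emulates a 100-SNP set: a 10-SNP block with
a configured squared correlation r² between consecutive genotype pairs
(0.2 or 0.8 in the standard designs) plus 90 independent null SNPs.
Block genotypes are produced by thresholding a latent AR(1) Gaussian at
the Hardy–Weinberg quantiles of the allele frequency; since
thresholding attenuates correlation, the latent correlation is
calibrated by root-finding on the exact bivariate-normal rectangle
probabilities so that the *genotype-scale* consecutive r² hits the
target. The allele frequency defaults to 0.30 — the design leaves it
open, and a common-variant frequency keeps all three genotype classes
well populated; conclusions rest on the power *ordering*, not absolute
power. The middle block SNP (index m_block//2) is causal by default,
with OR 1.1; the other nine block SNPs receive no direct effect — their
attenuated odds ratios arise purely through LD. Disease status is drawn
prospectively from the logistic model whose intercept is solved
numerically so the expected case fraction is 30%; a retrospective mode
that accrues an exact case count is available. The dataset (default
N = 20,000) is split at random into discovery and test halves,
discovery effect sizes are re-estimated per replicate, and the test
half alone is used for LD estimation and testing.

Scenario B ("real-data LD") is driven by any user-supplied genotype
panel; a 115-SNP synthetic block-structured panel (5-SNP AR(1) blocks)
ships as a stand-in for consortium data, which cannot be redistributed.
Association is induced by phenotype flipping: n controls homozygous for
the risk allele become cases and n cases homozygous for the protective
allele become controls, leaving the genotype matrix and total case
count untouched. The flip count is a required user parameter.

`run_experiment` is a pure function of (config, master seed): replicate
streams derive from the master seed by counter (`SeedSequence(seed,
spawn_key=(r,))`), so any replicate can be reproduced in isolation.
Rejection rates are exact counts of p < threshold with Clopper–Pearson
95% intervals; calibration is judged by whether the interval covers the
nominal level.

What the generator does *not* emulate: genotyping error, missingness,
population stratification, covariate structure, imperfect tagging of
untyped causal variants, and long-range or irregular empirical LD.
Passing calibration and power-ordering tests here therefore shows the
mathematics and the pipeline behave as derived under clean HWE sampling,
not that real-data gene rankings would be unchanged.

## Numerical choices

- Per-SNP discovery effects are 2-parameter logistic MLEs computed by a
  Newton solver vectorised across SNPs (closed-form 2×2 Hessian solve,
  convergence at 1e-8 on both updates, 50 iteration cap). It matches a
  conventional per-SNP GLM fit to ~1e-6 and makes 1,000-replicate
  experiments tractable on one CPU. |log OR| > 15 or a degenerate
  information matrix is treated as separation; such SNPs (and
  monomorphic ones) are excluded with a machine-readable reason.
- Eigendecomposition uses the symmetric solver; tied eigenvalues are
  harmless because only the spectral projector of each eigenspace
  enters the transform, which is basis-invariant (tested on an
  equicorrelation matrix against the closed form).
- The transform matrix is materialised only for M ≤ 5,000; above that it
  is applied as three matrix products, bounding memory at O(M²) for the
  eigenvectors rather than forming an additional M×M product.
- Correlation matrices are symmetrised and given an exact unit diagonal,
  so the trace identity Σλ_k = M holds to round-off; eigenvalues below
  −1e-8 raise, smaller negatives clip to zero.
- Experiments at the standard design (N = 20,000, M = 100, R = 1,000
  replicates) run in roughly 5–7 minutes per method set on one CPU;
  the test suite reuses one null run and one powered run for all
  calibration, uniformity and power-ordering checks, and the
  discovery-size monotonicity check uses 120 paired replicates.

## Known limitations

- LD is always estimated from the test genotypes; external reference
  panels are out of scope, as are shrinkage estimators of C beyond the
  ridge.
- β is passed through unchanged — no winsorizing or standardising.
- The PCA comparator's gene-exclusion behaviour will not exactly match
  other implementations' internal QC, so total analysed-gene counts can
  differ between methods on real data.
- With C estimated from N individuals rather than known, the adjusted
  score differs from the plain PRS by O(1/√N) sampling noise even for
  truly independent SNPs; the two tests' p-values then agree only to
  ~1e-2, with exact equality reserved for C = I itself.
- Competitive (baseline-adjusted) set testing and meta-analysis of
  discovery plus test data are not implemented.
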
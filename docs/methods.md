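# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `regulatlas`.

## Data model and conventions

Coordinates are 1-based inclusive (VCF convention); distances are absolute
bp differences. Dosages live in {0, 1, 2, NaN}; NaN is the dedicated
missing-call sentinel and downstream mean-imputation is always explicit.
Heterozygote phase is ignored ("0/1" and "1/0" both give dosage 1 — rare but
legal in inbred panels). MAF is computed after excluding missing calls.
Variant QC defaults keep sites with MAF > 0.05 and missing rate < 0.99; the
unusually permissive missing-rate ceiling is deliberate and matches the
panel this pipeline targets. Genes are kept per tissue when expressed
(count > 0) in strictly more than 50% of that tissue's samples ("more than"
is read as a strict inequality). Expression is log2(count + 1), z-scored
per gene within tissue; the pseudocount handles legal zero counts.

## REML core

All mixed models share one engine. For y = Cα + u + e with u ~ N(0, σ²ᵤR),
e ~ N(0, σ²ₑI), the relationship matrix R is eigendecomposed once
(R = UDUᵀ, small negative modes clipped at −1e−8·scale, anything worse is
rejected as non-PSD). After rotating y and C by Uᵀ, the restricted
likelihood is profiled over the intraclass correlation
h = σ²ᵤ/(σ²ᵤ+σ²ₑ) ∈ (0, 1): a 33-point grid bracket followed by bounded
Brent refinement (xatol 1e−10). Total variance is profiled out analytically.
The SE of ρ̂² = ĥ is the inverse square root of the numeric curvature of the
profiled restricted log-likelihood (central differences, step 1e−4). When R
is (a multiple of) the identity the likelihood is flat in h; a grid spread
below 1e−6 (or an eigenvalue spread below 1e−10) flags the fit as
unidentifiable (`converged=False`, ρ² = NaN) rather than returning an
arbitrary number. Boundary fits are reported at h ∈ [1e−6, 1−1e−6].

## Association scans

The default scan is EMMAX-style: variance components fit once under the
null, then every predictor tested by GLS with fixed V = σ̂²ᵤR + σ̂²ₑI.
Implementation: whiten by V^(−1/2) in the rotated basis, residualize
predictors against the covariates via a QR factorization, and read
β = x̃ᵀỹ/x̃ᵀx̃ with SE = (x̃ᵀx̃)^(−1/2). This is algebraically identical to
dense GLS with the projection matrix (verified to 1e−8 relative against an
explicit V-inversion oracle in the tests). Wald p-values use the normal
reference — standard for mixed-model association at these sample sizes.
An `exact` mode refits variance components per predictor for verification.
Monomorphic predictors (after per-variant mean imputation) are flagged and
reported with β = 0, p = 1.

Conditional analysis iterates: scan, take the smallest-p variant below the
threshold (ties broken by position, then lexicographic id), append its
dosage to the covariates, rescan; stop when nothing passes. The null
variance components are reused across rounds (the EMMAX convention).
Predictors that become collinear with selected covariates are skipped with
a warning. This is an individual-level re-specification of the
summary-statistic stepwise procedure used with large GWAS toolchains; with
individual data in hand it is the same loop without an LD reference panel.

## Effective number of markers

Mₑ uses the Li–Ji eigenvalue rule: per window of the variant correlation
matrix, Σᵢ [1(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)]. Windows slide (default 200 wide,
overlap 50); overlapping segments are counted once by subtracting the
segment's own Li–Ji count (inclusion–exclusion). A 1e−7 guard protects the
floor() discontinuity at integer eigenvalues, so exactly independent
markers give exactly M and perfectly duplicated pairs give exactly M/2.
Note the Li–Ji functional is not monotone under variant duplication in
general (the unit mass a duplicate adds can spread into fractional parts of
other eigenvalues); Mₑ ≤ M always holds and is what the tests assert.
Genome-wide thresholds are α/Mₑ.

## Tissue specificity

Per gene, log2 counts are z-scored with all tissues pooled (the contrast is
defined on a single pooled vector per gene), then each tissue is tested
one-vs-rest with a ±1 dummy plus intercept; the slope t is computed in its
equivalent pooled two-sample form, vectorized across genes, and the
equivalence to the explicit regression is property-tested. Candidates are
the top 5% by t per tissue (ties at the cutoff all retained; fewer than 20
genes yields an empty result with a warning). The fold-change filter uses
normalized counts with pseudocount 1: FC against each other tissue is
(median + 1)/(median_other + 1), and the median over other tissues must be
≥ 2. The alternative "fold against the pooled median of the other tissues"
is available behind a flag. Fold change is computed on the count scale, not
log2, because a fold of expression reads most naturally on counts and the
pseudocount handles zeros.

Enrichment is the hypergeometric upper tail over a user-supplied universe
with Benjamini–Hochberg FDR across sets and fold = (k/n)/(K/N); no organism
annotation database is bundled.

## Latent expression factors

Hidden technical/biological variation is captured per tissue by the first
k left singular vectors of the standardized expression matrix, rescaled to
unit variance (default k = 25, matching the number of latent covariates
standard for panels of this size; simulations here use smaller k matched to
their sample sizes). A deterministic SVD factor set is used because the
factors serve purely as nuisance covariates in the scans; the Bayesian
residual-factor model this replaces has near-identical correction behavior
in that role. Expression is standardized first and factors are passed as
covariates (no pre-residualization).

## eQTL atlas

Each gene is scanned genome-wide per tissue with the factors as fixed
covariates and the line-level kinship as random-effect covariance;
standardized expression makes betas comparable across tissues. Significant
genes get the conditional loop, and each selected variant becomes one
record with its round number. cis means same chromosome and within 1 Mb of
the gene's TSS (boundary inclusive); everything else is trans. LD is r² on
dosages (the toolchain convention; D′ is not used). eQTLs from all tissues
are grouped by union-find over pairs with r² > 0.2 (strict) and distance
< 500 kb (strict) on one chromosome, computed on the full panel; the
cluster representative is the smallest-p member (ties by position then id).
Cross-tissue comparison matches records by (gene, cluster) and reports the
Pearson correlation of paired betas and the sign-discordance fraction.

## Trait integration

The omics relationship matrix is A = ZZᵀ/g over standardized genes; PVE is
the REML intraclass correlation with R = A. TWAS tests each standardized
gene as a fixed effect with the A-background fit once under the null; the
strict threshold is 0.05/#genes and the lenient threshold 0.05/#associated,
with the associated count realized from the strict pass (the realized-count
rule is used because a fixed published count does not transfer across data
sets). Trait QTLs colocalize with a cluster when the cluster
representative lies strictly within 100 bp on the same chromosome
(measuring to the representative is the default; any-member matching is a
flag).

SMR: b_xy = b_GWAS/b_eQTL, T = z²_G z²_E/(z²_G+z²_E) ~ χ²₁, SE by the delta
method. HEIDI eligibility follows the published defaults of the SMR
method: eQTL p < 1.6e−3, r² with the top SNP in [0.05, 0.9], at most 20
SNPs kept by eQTL significance; fewer than 3 eligible SNPs leaves p
undefined with the count reported. The covariance of d = b_xy(i) −
b_xy(top) comes from first-order delta-method covariances of the effect
estimates (within-study cov = r·SEᵢ·SEⱼ, cross-study terms zero for
independent samples); T = Σ z²_d is referred to a weighted chi-square by
Satterthwaite moment matching on the eigenvalues of the correlation of z_d.
Monte-Carlo quadratic-form sampling was used as the oracle for this
approximation; under a simulated single-shared-causal-variant null with a
strong instrument, the empirical rejection rate at α = 0.05 is ≈ 0.03
(slightly conservative, as moment matching tends to be in the far tail).

The eGene-vs-random comparison is a two-sided Mann–Whitney rank-sum test on
−log10 p (robust to the heavy right tail), with an empirical p from
size-matched random draws without replacement. The eQTL-PVE comparison
builds a GRM from only the chosen variants and compares its REML PVE with
size-matched random variant sets; the empirical p is the fraction of random
PVEs at or above the observed one. Replication tests Pearson correlations
of expression against trait in an independent panel, with pairs under 3
complete observations skipped and sign agreement reported separately from
the p < 0.05 fraction.

## Synthetic data

Genotypes: two haplotypes per sample from a copying process — within an LD
block each variant copies the previous variant's allele on the same
haplotype with probability 1 − switch_prob, otherwise draws fresh from the
variant's frequency. switch_prob = 0 gives r² = 1 within a block,
switch_prob = 1 gives independent variants; one parameter tunes adjacent
r², the dosage domain is exact, and the process is fast. Base frequencies
are uniform on the MAF range; subpopulations (default Fst 0.1) perturb them
Balding–Nichols style. Positions are spaced ~2 kb apart on one chromosome
by default, so a 5,000-variant genome spans ~10 Mb and 1 Mb cis windows are
a meaningful fraction of it.

Expression: per tissue, log2-expression = gene baseline N(5, 1.5²) +
planted eQTL effects + shared latent factors + N(0, noise_sd²) noise, and
counts = round(2^log2x) floored at 0 — exponentiating Gaussian
log-expression matches the log2-then-standardize treatment downstream.
Planted effects act on the z-scored dosage in units of noise_sd (default
1), so an "effect 1 SD" eQTL shifts expression by one residual SD per
dosage SD; cis variants are drawn within 1 Mb of the gene's TSS (TSS are
anchored near variants so windows are never empty), trans variants outside
it. Effects are shared across tissues with a configurable
discordant fraction flipping the sign in one tissue. Default latent
structure is 5 factors with N(0, 0.5²) loadings — a variance share
comparable to noise, as hidden structure in real panels tends to be.
Tissue-specific genes get +log2(fold) in their tissue. One seed governs a
scenario; sub-streams per component are derived deterministically.

Traits: weighted sums of standardized causal-gene expression in one tissue
(default 100 causal genes — a polygenic but not omnigenic architecture),
optional direct variant effects, and Gaussian noise, with the parts
rescaled so the realized transcriptomic variance fraction equals the
target ρ². Replicated phenotypes for BLUP validation are the plain
two-way model y = μ + line + env + resid with stated variances.

What the generator does not emulate: realistic demography or recombination
maps, read-level count noise (counts are rounded log-normals, not
negative-binomial draws), dosage uncertainty, batch structure beyond
low-rank factors, and cross-tissue correlated noise. Passing tests
therefore validate the statistical machinery on data with the assumed
covariance structure; they do not certify behavior under real-data
artifacts such as mappability bias or expression outliers.

## Problem sizes

The validation suite uses the scales at which the statistical claims are
stated: dense-GLS oracle agreement on 50 random instances with n ≤ 100;
type-I error on 2,000 null variants at n = 300 under 3-subpopulation
structure; PVE recovery over 20 replicates at n = 300, g = 1,000; tissue
specificity on 4 tissues × 1,000 genes × 300 samples; HEIDI calibration
over 500 mediation-null regions of 30 SNPs at n = 500 per study; and one
full pipeline run at n = 300 lines, m = 5,000 variants, g = 1,000 genes,
3 tissues. These sizes keep a complete run on one CPU in a few minutes
while leaving every estimate's Monte-Carlo error well inside the asserted
bands.

## Known limitations

* EMMAX's fixed null variance components slightly deflate tests of very
  large effects; the exact mode exists for verification but is O(m) REML
  fits.
* The TWAS background includes the tested gene itself (proximal
  contamination), mildly shrinking large single-gene signals — the
  convention of omics-REML TWAS tools.
* HEIDI's Satterthwaite tail is conservative for small eligible-SNP counts.
* The Li–Ji Mₑ is a stand-in for other effective-test estimators and is
  window-dependent in strongly structured LD.
* Colocalization is a distance rule, not a posterior-probability model; it
  inherits the coarseness of published QTL coordinates.
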
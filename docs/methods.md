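# Methods

This note documents the models behind `pygsem`, the choices made where the
design was genuinely open, and what the synthetic-data validation does and
does not establish.

## The generative model

All internal computation is in standardized units: per-SD phenotype and
per-SD genotype, so every marginal estimate has standard error 1/√N and the
LDSC and SEM algebra never sees allele frequencies. Per-allele scaling by
√(2p(1−p)) is applied only when tables are written to disk, and undone on
read via beta = z/√N.

A `TruthModel` declares, for k traits: factor loadings Λ (k×f, on the
genetic-covariance scale), factor correlations Φ, residual genetic variances
ψ, and SNP heritabilities h² — with the constraint that
diag(ΛΦΛᵀ + diag(ψ)) = h². Per-SNP true effects for the causal fraction π of
M SNPs are drawn i.i.d. MVN(0, (ΛΦΛᵀ + diag(ψ))/(πM)), so the effects summed
over the genome reproduce the declared genetic covariance exactly in
expectation, and a zero-heritability trait receives exactly zero effects.

Linkage disequilibrium is block-diagonal with exchangeable within-block
correlation r = √r²; block sizes and r² values cycle through
(10, 25, 50, 100) × (0.05, 0.15, 0.3, 0.5) across 22 chromosomes. This keeps
the LD score ℓⱼ = 1 + (b−1)r² computable in closed form, makes clumping
exact (one independent signal per block), and — because ℓ varies across
blocks — keeps the LDSC slope and intercept identified. Marginal (GWAS)
effects are the LD-smoothed true effects Rβ; estimation noise is drawn
independently per SNP with cross-trait covariance
overlap_frac × phenotypic_corr_overlap / √(N_t N_s), which is exactly the
quantity the cross-trait LDSC intercept estimates.

Binary traits are emulated through an effective sample size
4/(1/cases + 1/controls) rather than liability thresholds: the pipeline
consumes only (z, N), so the liability scale never enters. A small fraction
of rows receives sub-threshold INFO or allele frequencies, and another a
palindromic allele pair, so the QC and harmonization stages are exercised.

Planted MR instruments occupy distinct LD blocks (middle SNP; the block's
polygenic background is cleared so the planted effect is what the
instrument's marginal estimate converges to). An instrument's outcome effect
is causal_effect × exposure effect + pleiotropy_shift. Exposure signs are
random by default; `effect_sign="positive"` keeps them orientation-
consistent, which matters for directional-pleiotropy scenarios — after the
MR orientation step a constant direct effect on randomly signed instruments
is *balanced*, not directional.

## LD score regression

χ² = z² is regressed on ℓⱼ; slope × M/N̄ is h² (observed scale) and the
intercept is 1 under the null. Cross-trait: z₁z₂ on ℓⱼ, slope × M/√(N̄₁N̄₂)
is the genetic covariance and the intercept the overlap term. Weights are
the standard two-step heteroskedasticity weights: 1/ℓ first, then
1/(ℓ·fitted²) with the fitted mean floored at 0.1. M is the number of
regression SNPs (the self-contained synthetic setting has no external
reference panel); when a chromosome-parity subset is analysed, the slope is
converted with the *full* frame's M, so odd- and even-chromosome runs both
estimate the genome-wide S (their average matches the all-chromosome run
within sampling error — the invariant the parity split relies on).

Standard errors come from a delete-one block jackknife over 200 contiguous
genome-ordered blocks (configurable); weights are held fixed across
deletions. `build_S_V` runs all k(k+1)/2 regressions on one shared block
partition and assembles V as the jackknife covariance of the delete-one
estimates of vech(S), so V carries the dependence between S elements that
the structural models need. Genetic correlations are rg = S_ij/√(S_ii S_jj)
with the jackknife applied to the ratio itself, normal-approximation
p-values and Benjamini–Hochberg FDR across pairs (the standard reading of
"false-discovery" correction; the procedure is configurable in principle
but BH is the default and only implementation).

Intercept denoising: the univariate and cross-trait intercepts are nuisance
parameters re-used by the latent-factor GWAS as the per-SNP noise
correlation. At desk-scale M their estimation noise (SE ≈ 0.02–0.05) is
material: propagating raw estimates inflates the null Q_SNP mean by ~9%.
`GeneticCovariance.intercepts_denoised()` therefore snaps intercepts within
2 jackknife SEs of their null value (1 on the diagonal, 0 off it) to that
null; genuinely overlapping cohorts (intercept ≈ overlap × phenotypic
correlation, many SEs from 0) are unaffected. With full-scale inputs
(millions of SNPs) the correction is a no-op.

## Factor models

PCA/Kaiser and EFA run on the smoothed genetic correlation matrix of the
odd-chromosome S. EFA is iterated principal-axis factoring followed by
varimax and promax (κ = 4) rotation; promax is the default because the
retained genetic factors are expected to be intercorrelated, and an oblique
pattern plus factor correlations is what a subsequent CFA needs. Heywood
cases are clipped at communality 0.999 with a warning. A salience threshold
(default |λ| ≥ 0.25, assignment by primary loading) turns the pattern into a
proposed CFA structure.

Confirmatory and structural models minimize the diagonally weighted least
squares discrepancy Σᵢ (sᵢ − σᵢ(θ))²/Vᵢᵢ over the free parameters of a
LISREL-style model: Σ(θ) = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ. Factors with no fixed
loading are identified by unit variance (so loadings and paths are on the
standardized genetic-factor scale); a fixed loading switches that factor to
marker identification with a free variance. Optimization is L-BFGS-B with
numerical gradients and three jittered starts (fixed seeds; gradient
tolerance 10⁻⁸); residual variances are bounded at zero.

Inference uses the full V: sandwich covariance
(ΔᵀWΔ)⁻¹ΔᵀWVWΔ(ΔᵀWΔ)⁻¹ with Δ = ∂σ/∂θ. The model test statistic is the
residual-based quadratic form r'[V⁻ − V⁻Δ(Δ'V⁻Δ)⁻¹Δ'V⁻]r, which is
asymptotically χ²(p − q) for any consistent estimator — the natural choice
when the fitting weight is only diag(V). It is exactly zero for a saturated
model; unlike the minimized discrepancy it is not guaranteed monotone under
nesting in finite samples (the discrepancy itself is, and that is what the
nesting test asserts). SRMR is the RMS standardized residual over all unique
elements; CFI compares against the diagonal (no-covariance) baseline fitted
with the same machinery, reported as 1 with a flag if the baseline is
degenerate (χ²_b ≤ df_b).

The loneliness structure is a single-indicator latent: loading fixed at 1,
indicator residual fixed at 0, disturbance free — a clean way to give a
single trait latent status so it can appear on the left of regressions.
Three models are fitted: separate bivariate regressions on each factor
(each on the sub-matrix of that factor's indicators plus the loneliness
trait), the joint adjusted regression with free factor intercorrelations,
and the constrained model with all but the designated target path fixed to
zero. Under near-collinear factors (Φ ≈ 0.9) the joint model reproduces the
reversal phenomenon — nuisance paths flip sign while the target inflates —
and the constrained model stays unbiased; the validation asserts exactly
this contrast.

## Latent-factor GWAS and Q_SNP

Two-stage estimation: the measurement model is fitted once without SNPs and
held fixed (orders of magnitude faster than a per-SNP joint refit and
asymptotically equivalent when the per-SNP information about the loadings is
negligible). For each SNP, with b the per-trait standardized betas, λ the
target factor's loadings and W = diag(1/se²):

- effect:  β_latent = λᵀWb / λᵀWλ, sandwich variance λᵀWΩWλ/(λᵀWλ)² with
  Ω = D·C·D, C the (denoised) intercept matrix, D = diag(se);
- heterogeneity: Q_SNP = bᵀΩ⁻¹b − (λᵀΩ⁻¹b)²/(λᵀΩ⁻¹λ), the χ² difference
  between the saturated independent-pathways model and the common-pathway
  model under the full sampling covariance; df = n_indicators − 1.

Because C is constant across SNPs, the whole genome is computed with a few
matrix products. Under a true common pathway Q_SNP is central χ²(df)
regardless of loading-estimation error (the projection removes one degree
of freedom whatever the direction); SNPs with Q_SNP p < 5×10⁻⁸ are
excluded before the factor is used as an MR exposure (configurable to both
sides). The output table is sumstats-shaped with N = 1/se² (the per-SD
effective sample size), so MR consumes it like any trait.

## Mendelian randomization

Instrument selection is greedy clumping: candidates with p below the
threshold visited in ascending p (ties by position then id); an accepted
index SNP removes later candidates on the same chromosome within the window
(strict <, measured in bp from the index SNP) whose reference r² exceeds
the cap (strict >). SNPs absent from the LD reference are treated as
independent and logged. Harmonization aligns outcome effects to the
exposure effect allele (sign flip on swapped alleles, palindromic and
mismatched SNPs dropped) and then orients all exposure betas positive.

Estimators:

- **IVW** — weighted regression of b_Y on b_X through the origin, weights
  1/se_Y²; multiplicative random-effects SE (inflation max(1, √(Q/df))) by
  default, fixed-effects available.
- **MR-Egger** — same with a free intercept (directional pleiotropy);
  I²_GX = (Q_GX − (n−1))/Q_GX from the exposure betas gauges violation of
  the no-measurement-error assumption.
- **Weighted median** — interpolated weighted median of per-SNP Wald
  ratios, inverse-variance weights on the first-order delta-method ratio
  SEs; parametric-bootstrap SE (1,000 draws, seeded).
- **Weighted mode** — mode of the weight-normalized Gaussian-kernel density
  of the ratios, modified Silverman bandwidth (0.9·min(sd, MAD/Φ⁻¹(0.75))·
  n^(−1/5)) × a configurable factor, maximized on a 2,000-point grid over
  the data range; bootstrap SE.
- **RAPS** — maximizes the Gaussian profile quasi-likelihood of the slope
  accounting for measurement error in b_X, with an optional additive
  overdispersion variance (log-parameterized, Nelder-Mead) and optional
  Huber loss; SE from the numerical observed information. Designed for the
  relaxed-threshold (5×10⁻⁷) sensitivity run where weak instruments dilute
  IVW.

Diagnostics: Cochran's Q about the fitted slope (df = n−1, or n−2 with the
Egger intercept); Steiger directionality with r² = z²/(z²+N) per SNP and a
strict exposure-greater rule; a warning below 10 instruments. Confidence
intervals are normal-approximation throughout (a t convention is possible
but not default). The bidirectional driver runs
select → harmonize → Steiger → all estimators for both directions at the
primary (5×10⁻⁸) and sensitivity (5×10⁻⁷) thresholds, reporting a direction
without usable instruments as not estimable rather than failing the run.

## Pipeline, determinism and problem sizes

One flat YAML config drives the full run. A single global seed fans out to
per-stage seeds by CRC-32 hashing of the stage name, so stages are
individually reproducible and a rerun with the same config is byte-identical
(SHA-256 hashes of all tabular outputs are recorded in the run report;
images are excluded from the hash set). The config validator enforces
threshold ranges, a mandatory seed, and warns when EFA and CFA are assigned
the same chromosome parity.

Default problem sizes were chosen so that each validation stage resolves its
estimand comfortably on one CPU: ~50,000 SNPs on 22 chromosomes (≈2,273 per
chromosome), 10–11 traits with heritabilities 0.04–0.41 mirroring the
published range for these phenotype classes, N = 20,000–100,000 per trait,
200 jackknife blocks, 12 planted instruments per causal direction with
|effect| = 0.05–0.06 (z ≈ 8–13 at the paired N). The demo pipeline and the
full validation suite each run in minutes.

## What the synthetic validation does and does not show

The generator reproduces the *first-order structure* real multi-trait GWAS
data: polygenic architecture with declared factor structure, LD-induced
inflation of marginal effects, overlap-induced noise correlation, QC-failing
rows and strand-ambiguous markers, and genome-wide-significant loci with
known causal content. Passing tests therefore establish that the estimators
recover what they claim to estimate under their own assumptions, with
calibrated uncertainty.

It does not emulate: realistic MAF spectra or MAF-dependent architectures,
long-range or population-specific LD (blocks are exchangeable and
chromosome-local), liability-scale effects for binary traits, or the X
chromosome. Two desk-scale artefacts deserve note. First, compressing a
genome into ~50k SNPs concentrates per-SNP effects, so a fully heritable
latent factor yields many genome-wide-significant background loci; in the
demo pipeline these enter the factor-to-loneliness MR direction alongside
the planted instruments and dilute it toward the background slope — the
controlled two-trait scenarios, where background polygenicity cannot reach
significance, are the clean causal-recovery checks. Second, LDSC sampling
noise per correlation element is ≈0.03–0.07 at M = 50k regardless of N, so
single-run loading recovery is noise-bounded; point-recovery claims are
therefore made on medians across seeds, and single runs are checked against
their own sandwich SEs.

## Known limitations

- DWLS with diag(V) weights is the convention implemented; full-V weighted
  least squares is not offered.
- No liability-scale conversion for binary traits (effective-N observed
  scale throughout).
- No multivariable MR, contamination-mixture or colocalization methods.
- The latent-free spec syntax covers measurement, latent regression and
  (co)variance statements only; indicator-level cross-loadings constraints
  beyond fixing values, and equality constraints across parameters, are not
  expressible.
- Clumping uses the synthetic block-diagonal reference; there is no
  external-panel r² computation.
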
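# Methods

## Model and assumptions

`mrmediate` works entirely on GWAS summary statistics: per-SNP effect
sizes β, standard errors, effect-allele frequencies, p-values and sample
sizes for each trait. A valid instrument must satisfy the three
instrumental-variable conditions — association with the exposure,
independence from confounders, and exclusion (effect on the outcome only
through the exposure). The estimators make the usual two-sample
assumptions: non-overlapping (or effectively non-overlapping) samples,
effects on a scale where a linear SNP–trait model is adequate (log-odds
for binary traits), and known per-SNP outcome standard errors.

### Univariate estimators

With harmonized per-SNP effects (β̂ₓⱼ, β̂ᵧⱼ, σᵧⱼ):

* **IVW** is the zero-intercept weighted regression of β̂ᵧ on β̂ₓ with
  weights wⱼ = 1/σᵧⱼ²; algebraically the inverse-variance meta-analysis of
  per-SNP Wald ratios β̂ᵧⱼ/β̂ₓⱼ with weights β̂ₓⱼ²/σᵧⱼ². The fixed-effects
  SE fixes the residual variance at 1 (SE² = 1/Σwβ̂ₓ²); the random-effects
  variant multiplies it by max(1, √(Q/(n−1))), with Q the weighted
  residual sum of squares. The pipeline's primary estimate is
  fixed-effects, switching to random effects when the Cochran-Q p-value
  falls below 0.05.
* **MR-Egger** adds a free intercept after orienting rows so β̂ₓ ≥ 0; the
  intercept estimates directional pleiotropy, the slope remains consistent
  under the InSIDE assumption. Slope and intercept SEs carry the
  max(1, √(Q/(n−2))) multiplier.
* **Weighted median** orders Wald ratios and interpolates the ratio at
  centred cumulative weight 0.5 ((cumsum(w) − w/2)/Σw); consistent when
  more than half the weight lies on valid instruments.
* **Simple/weighted mode** maximize a normal-kernel density of the Wald
  ratios (weights 1 or β̂ₓ²/σᵧ²), bandwidth 0.9·min(sd, MAD)·n^(−1/5)
  scaled by a configurable factor; consistent when the largest group of
  instruments is valid. The point estimate refines a 2048-point grid by
  bounded scalar minimization; if all ratios coincide the estimate is that
  ratio with SE 0.
* Median and mode SEs come from a seeded parametric bootstrap (resampling
  β̂ₓⱼ, β̂ᵧⱼ from their reported normals; default 5000 replicates, chosen
  for sub-second runtime at a few hundred SNPs — the point estimates do
  not depend on it).

All p-values are two-sided normal; odds ratios use exp(β ± 1.96·SE).
The 1.96 multiplier (not 1.959964) reproduces published 6-decimal CI
bounds exactly.

### Sensitivity battery

Cochran Q with df = n−1 around the IVW slope; I² = max(0, (Q − df)/Q)
labelled none / mild (0–25%) / moderate (25–50%) / high (>50%).
The Egger intercept is called pleiotropic at p < 0.05. Leave-one-out
refits IVW dropping each SNP (same effects-model rule) and flags a SNP as
influential when the shift exceeds a configurable multiple (default 2) of
the refit's SE — the refit SE, not the full-sample SE, because a gross
outlier inflates the full-sample random-effects SE and would mask itself.
The Steiger test sums per-SNP variance explained 2β²·MAF(1−MAF) on each
side (clipped to [0,1]), calls the direction correct when the exposure
side explains more, and computes a p-value by comparing the implied
correlations √R² through Fisher's z with 1/(N−3) variances. R² is clipped
just below 1 before atanh so that synthetic data whose summed R² exceeds 1
stay finite. For a binary outcome R² is computed on the observed log-odds
scale with no liability-scale correction. Funnel data (ratio vs precision)
are exported, not rendered or formally tested.

### Harmonization

Outcome rows are aligned to the exposure's effect allele: identical coding
is kept; swapped coding negates β and complements the frequency; strand
complementing is attempted before declaring a pair incompatible.
Palindromic SNPs (A/T, C/G) cannot be resolved by alleles alone: the
default policy drops those with exposure EAF in [0.42, 0.58] and aligns
the rest by frequency concordance (flipping when the two EAFs straddle
0.5); `drop-all` and `keep` are available. Rows dropped for any reason are
retained in the output with an `action_taken` reason and excluded from
estimation.

### Instrument strength

R² per SNP uses the standard variance-explained form 2β²·MAF(1−MAF). A
printed variant that is linear in β circulates in some sources; it is
dimensionally inconsistent with a variance fraction, so the quadratic form
is the default and the linear one is retained only as an `as-printed`
audit mode. The F-statistic is evaluated per SNP from its own R² with the
set-level k (the clumped-set size), in a single pass; an iterative variant
that re-derives k after each removal is available behind
`InstrumentConfig(iterative_f=True)`. Clumping is greedy on ascending
p-value with lexicographic SNP-id tie-break, giving order-invariant,
deterministic output.

### Multivariable MR and mediation

MVMR instruments are the union of each exposure's genome-wide-significant
SNPs, jointly re-clumped ranking by the minimum p across exposures. The
estimator is the zero-intercept weighted multiple regression of outcome
betas on the exposure-beta matrix (weights 1/σᵧ²), SEs with the
max(1, √(Q/(n−p))) multiplier. An all-zero exposure column is treated as a
nuisance-free exposure (direct effect 0, p = 1) rather than an error;
genuinely dependent columns raise a collinearity error naming the
exposures involved. A heuristic conditional instrument-strength F (mean
weighted squared residual association after partialling out the other
exposures) is reported per exposure and never used for filtering.

Mediation composes β_A (exposure → mediator, univariate MR) with β_B
(mediator → outcome direct effect, MVMR):

    β_M = β_A·β_B,    SE_M = √((β_A·SE_B)² + (β_B·SE_A)²).

The classification follows causal stepwise logic: the indirect effect is
significant when both components are, or failing that when the Sobel test
(z = β_M/SE_M) is; given a significant indirect effect, a non-significant
exposure direct effect β_C′ (from MVMR) means complete mediation; a
significant β_C′ with sign opposite to β_M is a covering (suppression)
effect reported as |β_M/β_C′|·100%; same-signed effects are partial
mediation reported as β_M/β_C·100% against the univariate total effect
β_C. Both denominators are stored so either convention can be audited.
Note the SE_M formula treats β̂_A and β̂_B as independent; when both draw
on the same mediator GWAS their errors correlate slightly, which is one
reason measured 2·SE_M coverage sits within a fraction of a percent of
nominal rather than exactly on it.

## The synthetic generator

`simulate_triple` emulates a three-trait summary-statistics study under
the structural chain

    β_med = a·β_exp + ε_med,    β_out = c_direct·β_exp + b·β_med + α + ε_out,

per SNP, with α a constant pleiotropy intercept on instrument SNPs and
ε the optional SNP-specific heterogeneity (sd `heterogeneity_sd`).
The exposure and the mediator each carry their own instruments: true
effects drawn from a half-normal of scale `beta_gx_scale` truncated so the
true z-score clears genome-wide significance at the trait's sample size,
with the effect allele coded trait-increasing (the orientation
summary-data MR tools standardize to — this is also what makes a constant
pleiotropy intercept *directional* in the MR-Egger sense; with random
signs it would cancel under Egger's orientation). Mediator-specific
instruments are essential: without them the mediator's only genetic
variation is a·β_exp plus noise, the MVMR design matrix has no exogenous
mediator variation, and the mediator's direct effect is unidentified.
Observed betas add exactly normal noise with the analytic SE
1/√(2·N·MAF(1−MAF)); no other noise touches the SEs. Null SNPs have zero
effects everywhere. LD is near-identity with optional equicorrelated
blocks co-located within the clumping window; all other SNPs are spaced
far apart across chromosomes. A configurable fraction of rows is emitted
palindromic, and a fraction of mediator/outcome rows with swapped allele
coding, to exercise harmonization. One integer seed fixes every draw;
identical configurations produce byte-identical tables.

### Default design point and what it does (and does not) represent

Defaults: 200 instruments per heritable trait, 50 null SNPs, N = 300,000
per trait, MAF ~ U(0.05, 0.5), `beta_gx_scale` = 0.2, a = 0.1, b = 0.07,
c_direct = 0, no pleiotropy or excess heterogeneity, 5% palindromic and
20% allele-flipped rows. Effect magnitudes on the outcome scale
(~10⁻³–10⁻²) match the log-odds magnitudes typical of summary-level
studies of a common binary outcome. The instrument-effect scale is set so
that per-SNP F — computed, per this package's convention, from the
per-SNP R² with the set-level k — clears the F ≥ 10 gate at these sample
sizes; with k ≈ 200 that requires per-SNP R² above ~0.7%, which is far
stronger than real per-SNP effects on complex traits. Consequently the
generator validates the pipeline's arithmetic, gates and calibration, not
the power of realistic GWAS designs: passing tests show the machinery is
correct under strong instruments, and say nothing about weak-instrument
regimes, sample overlap, LD misspecification from real reference panels,
or case-control liability-scale effects (a binary outcome is emulated
only through effective sample size).

## Numerical and procedural choices

* Ties in clumping broken lexicographically; clump output invariant to
  row permutation.
* Screening gates use raw p < 0.05 with Steiger direction TRUE and
  Steiger p < 0.05 required at every gate; no multiple-testing correction
  by default (Bonferroni/FDR available via `multiple_testing`).
* Pairs with fewer than three instruments stay in the causal screen but
  skip the pleiotropy and leave-one-out checks.
* Zero-spread ratio sets short-circuit the mode estimators; Wald ratios
  are undefined (error) at β̂ₓ = 0.
* Mediation CIs are β ± 1.96·SE from the stated SE formula.
* Test and validation problem sizes: calibration uses 1000 replicates of
  50-instrument studies; recovery uses 100 replicates of the default
  design point; these sizes keep the full validation suite to a few
  minutes on one CPU while leaving binomial tolerances meaningful.

## Known limitations

* No MR-PRESSO/contamination-mixture/RAPS estimators; no MVMR-Egger or
  MVMR-median; one mediator per model.
* No liability-scale conversion for binary traits; Steiger R² is on the
  observed scale.
* LD handling is matrix-based; no reference-panel computation, proxy
  search or PLINK-style genotype clumping.
* The per-SNP-F-with-set-k convention makes F stringent for large
  instrument sets (F scales like 1/k at fixed per-SNP R²); the iterative
  mode mitigates but does not remove this.
* The delta-method SE_M ignores the β̂_A–β̂_B covariance induced by a
  shared mediator GWAS (see above).
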
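# Methods

This note documents the statistical model behind `smoketrace`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions the implementation commits to. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## 1. The causal model

Two correlated exposures proxy two components of smoking:

- **NMR** (nicotine metabolite ratio, SD units): the speed of nicotine
  metabolism. Higher NMR ⇒ less circulating nicotine per cigarette, and (a
  feedback the model encodes with coefficient λ) a tendency to smoke more.
- **CPD** (cigarettes per day, 5 ordered bins with mean 3 and SD 1 among
  smokers): smoke exposure, nicotine included.

Each outcome Y receives a direct effect θ_NMR per SD of NMR (the
nicotine-per-cigarette path, reported sign-flipped as "effect of increased
nicotine exposure") and θ_CPD per SD of binned CPD (the smoke path), plus a
shared standard-normal confounder U. Never smokers have genotypes and a
latent metabolism phenotype but zero smoke and zero nicotine exposure, so
among them any genotype-outcome association must come from horizontal
pleiotropy (or, in real data, misreport/stratification) — which is exactly
why the pipeline runs never-smoker analyses as a negative control.

In a two-sample design the model is estimated entirely from summary
statistics: per-SNP exposure effects γ̂ⱼₖ (k = NMR, CPD) from two
non-overlapping exposure GWAS, and outcome effects Γ̂ⱼ from a third cohort.

## 2. Estimators

All estimators weight by the inverse outcome variance wⱼ = 1/se(Γ̂ⱼ)².

- **IVW**: through-origin WLS of Γ̂ on γ̂; β̂ = Σwγ̂Γ̂ / Σwγ̂². Default variance
  model is multiplicative random effects — se inflated by
  max(1, √(Q/(L−1))) — the dominant convention for summary-data MR; the
  fixed-effect model is available by flag and is what the calibration tests
  pin (under homogeneity with known variances it is exact).
- **MR-Egger**: SNPs are re-oriented so γ̂ⱼ ≥ 0, then WLS with intercept.
  The intercept estimates directional pleiotropy; inference uses t with
  L−2 df (honesty at small L). Orientation makes the fit invariant to
  allele-frame choices; the analogous MVMR-Egger orients on one chosen
  exposure (default NMR, the headline effect) and reports that orientation —
  no invariance across orientations is claimed because none holds.
- **Weighted median**: inverse-variance-weighted median of Wald ratios
  Γ̂ⱼ/γ̂ⱼ, linear interpolation of the cumulative weight at 0.5; consistent
  when ≥ half the weight is valid. SE by parametric bootstrap (resampling
  γ̂ⱼ, Γ̂ⱼ from their sampling normals; n_boot default 5,000, seed required).
- **Weighted mode**: argmax over a 512-point grid of a normal-kernel weighted
  density of the Wald ratios. Bandwidth = φ · 0.9 · min(sd, IQR/1.349) ·
  L^(−1/5) (modified Silverman on the ratio spread), φ default 1; grid spans
  the ratio range ± 3 bandwidths; degenerate spread returns the common ratio.
  As φ → ∞ the estimate approaches the weighted mean (tested).
- **MVMR-IVW / MVMR-Egger**: WLS of Γ̂ on the L×K matrix γ̂ without/with
  intercept; Q has L−K (resp. L−K−1) df. Rank-deficient designs raise a
  collinearity error — including an all-zero exposure column, whose
  minimum-norm solution would equal the univariable fit (the nested-model
  identity is verified against an independent lstsq oracle in the tests, and
  the estimator reports the degeneracy instead of silently picking a
  solution).
- **Conditional F** (per exposure k): WLS of γ̂·ₖ on the other exposures'
  columns with weights 1/se(γ̂ⱼₖ)², through the origin; F = Q_x/(L−K+1).
  Covariances between exposure GWAS are ignored — the cohorts do not overlap
  by construction — so this is the simplified, equal-weight version of the
  statistic. Threshold 10 is the conventional adequacy bar.
- **Wald ratio se**: first-order delta method |se(Γ̂)/γ̂| only; second-order
  terms are negligible at the instrument strengths simulated (F ≫ 10).

P-values are two-sided normal except the Egger family (t with the fit's
residual df). Odds ratios exponentiate the estimate and its CI bounds.

## 3. Harmonisation rules

The first exposure dataset defines the allele frame. Per variant: exact
allele match ⇒ keep; swapped ⇒ negate the other dataset's beta and reflect
its eaf; complement (strand flip) resolved before comparison; palindromic
(A/T, C/G) variants are kept only when both effect-allele frequencies fall
outside the ambiguity band (default eaf ∈ [0.30, 0.70]) on the same side —
anything else, including a missing eaf, drops the variant. Every drop is
logged with a reason, so retained + excluded = candidates always.

Clumping is greedy on the p-value ranking (ties broken by rsid): keep a
variant iff every already-kept variant is beyond the window (default
10,000 kb, or another chromosome) or below the r² ceiling (default 0.001).
Proxy search returns the maximal-r² variant ≥ 0.8, ties broken by distance
then rsid. These defaults are the field's standard MR instrument-selection
settings; the source analyses do not print theirs, so all three are
explicit, overridable knobs.

Instrument selection is restricted to each exposure GWAS's own
*conditionally independent* panel (the published 7- and 55-SNP lists). This
matters in the synthetic world: with λ > 0 the NMR loci genuinely reach
genome-wide significance for CPD at n = 337,334, so a naive marginal scan
would return 62 "CPD instruments". Selection-by-panel mirrors what the
source GWAS publish, while harmonisation still reads both exposures' effects
for every union variant from the full summary statistics.

## 4. The generator's calibration

**Genetic architecture.** 7 NMR loci and 55 CPD loci, biallelic, independent
(conditional independence of the published panels is represented as exact
independence), mafs spread over (0.15, 0.40) and (0.10, 0.45), per-allele
effects solved for equal per-locus variance shares: Σ 2p(1−p)a² = h². For NMR
h² = 0.38 directly. For CPD the target 4% applies to the *binned* variable:
discretising a unit-normal latent into bins with probabilities
(0.07, 0.22, 0.42, 0.22, 0.07) — chosen symmetric with exact mean 3 and
SD 1 — attenuates any covariance with the latent by ρ = cov(bin, latent) ≈
0.953, so the latent genetic variance is set to 0.04/ρ² ≈ 0.0440 and the
regression of bins on the 55 genotypes recovers R² ≈ 4% (a Stein-identity
argument, verified empirically in the acceptance tests). The NMR→CPD
feedback λ (default 0.1 SD/SD; asserted qualitatively but never quantified in
the source, hence a free knob) enters the latent before binning; the latent
residual variance is 1 − v − λ², and configurations that push this ≤ 0 are
rejected as infeasible.

**Outcomes.** Continuous: Y = m_s + θ_NMR·NMR + θ_CPD·(bin−3) + c·U + ε with
m_s and var(Y) matched to the published per-stratum means/SDs (never-smoker
outcomes drop both θ terms). Binary: unit-variance liability thresholded at
the stratum prevalence. The configured binary truths are log odds ratios;
they are converted to liability loadings by θ_liability =
θ_logOR · μ(1−μ)/φ(Φ⁻¹(1−μ)). Under a Gaussian systematic score the average
derivative of the case probability equals φ(threshold)·θ_liability exactly,
so the full downstream pipeline — linear GWAS on the 0/1 trait, then division
by μ(1−μ) — recovers the configured log-OR without further correction. This
is what makes "the generator's truth" and "the estimator's estimand"
coincide, and it is the property the parameter-recovery tests check.

Default truths are the study-scale multivariable estimates: heart rate
+4.22 bpm (CPD) and −0.30 bpm (NMR) per SD among current smokers; FEV-1
−272.36/−17.77 mL; FVC −195.31/−13.50 mL; COPD log(7.24)/log(1.03); CHD
log(1.32)/0; lung cancer log(2.94)/0 with ever/never strata only (the
lung-cancer source is a case-control consortium: 57%/24% case fractions, no
current/former split — the pipeline must and does tolerate missing strata).
COPD among never smokers is printed only as "<1%"; the packaged value is the
0.5% midpoint because the liability threshold needs a number. Stratum sizes
default to the cohort's 49,721 current / 163,620 former / 258,056 never,
jointly downscalable.

**Interpretive constructions** (not printed in the source, documented as
package choices): the circulating-nicotine dose carried on each cohort is
dose = bin · max(1 − η·NMR, 0.05) with η = 0.3; the cotinine-style
alternative exposure is 0.4·(standardised dose) − 0.5·NMR + noise; the
`metabolism_pleiotropy` knob adds a metabolism→outcome liability path that
the cotinine model mislabels (a spurious direct effect appears) while the
NMR model absorbs it into the metabolism exposure itself — the qualitative
contrast the supplementary analyses show. Magnitudes are free parameters; no
quantitative supplementary target is claimed.

**Pleiotropy injection** gives the first ⌈proportion·L⌉ loci of the target
panel (a fixed, auditable choice) a per-allele direct effect on every
outcome — constant-sign ("directional") or alternating ("balanced") — in
outcome-SD units for continuous and liability units for binary traits,
active in all strata including never smokers.

**LD panels** are synthetic: block members copy the base genotype with
probability √r², giving pairwise correlation √r² and hence r² against the
base; the emitted table holds the empirical r² of the generated genotypes.
Blocks share one maf (unequal mafs cannot reach a positive r² target under
this mechanism and are rejected).

**What the generator does not emulate** — and therefore what a green test
does *not* establish: realistic LD from reference haplotypes, age/sex
covariate structure and mixed-model relatedness corrections, imputation
uncertainty, sample overlap between cohorts, selection into the cohort
("healthy volunteer" bias), and the exposure-GWAS covariate adjustments
(e.g. BMI adjustment of the NMR GWAS). Estimator behaviour under those
violations is untested here; the never-smoker machinery detects injected
pleiotropy, not cohort-selection artefacts.

## 5. Diagnostics and controls

- Q > nSNP is the working heterogeneity rule reported as a flag on every
  row, alongside the χ² p-value. Because Q ~ χ²(L−1) exceeds L about 44% of
  the time under perfect homogeneity, the never-smoker *verdict* requires
  both a non-null estimate (p < 0.05) and heterogeneity (Q p < 0.05); Q > L
  alone never fails a control check.
- Positive control: the flipped NMR direct effect on heart rate should be
  positive and distinguishable from zero. Negative controls: the flipped NMR
  effect on lung cancer consistent with null; never-smoker estimates null.
  Checks whose rows are absent return "indeterminate" rather than guessing.
- No multiple-testing correction is applied anywhere; per-outcome CIs are
  reported as-is and flags are descriptive.

## 6. Numerical conventions and edge cases

- 95% CIs use the full-precision normal 0.975 quantile (1.959964…), not a
  truncated constant; Egger-family CIs use the t quantile at the fit's df.
- Effect scales are an explicit enum; applying the liability transform to
  anything but linear-scale binary statistics is a state error (double
  transformation is impossible by construction). The transform preserves
  β/se exactly, so p-values are untouched.
- `to_odds_ratio` accepts se = 0 as the degenerate point-mass limit and
  rejects negative se.
- GWAS emulation is per-locus simple least squares on dosage within a
  stratum (the synthetic model has no covariates); binary traits are analysed
  on the linear scale and rescaled at the *observed* case fraction. P-values
  are floored at 1e-300 to stay in (0, 1].
- Genotypes are drawn as two Bernoulli trials via float32 uniforms (3×
  faster than the generic binomial sampler, identical distribution);
  phenotype scores use float32 matrix products with float64 accumulation
  downstream — differences are far below every test tolerance, and the GWAS
  itself runs in float64.
- Bootstrap and simulation seeds are mandatory and all derived seeds stay
  below 2³¹; identical config + seed gives byte-identical result CSVs
  (floats printed at 10 significant digits).
- Weighted-median interpolation clamps at the extreme ratios when the
  cumulative weight at 0.5 falls outside the midpoint range; bootstrap draws
  that would cross zero exposure effect are nudged to the smallest positive
  float (a measure-zero guard).

## 7. Known limitations

- The conditional F ignores exposure-GWAS covariance (see §2); with
  overlapping samples it would be anticonservative.
- MVMR-Egger estimates depend on the orientation exposure; both runs are
  available but the package reports one at a time.
- The weighted median/mode use simple inverse-variance weights (penalised
  variants not implemented); MR-PRESSO-style outlier removal, Steiger
  filtering and weak-instrument-robust MVMR are out of scope.
- Liability-scale recovery of log odds ratios is exact only in the
  average-derivative sense; at very large per-SNP effects or very skewed
  prevalences the first-order correspondence would degrade (irrelevant at
  the simulated per-SNP effect sizes).
- The never-smoker control detects pleiotropy that is *present in the
  generator's never smokers*; collider bias induced by stratifying on
  smoking status itself is representable (U is a shared cause) but not
  exercised by the default tests.
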
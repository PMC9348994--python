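# Methods

`vitdmr` implements, end to end, a cohort analysis of serum
25-hydroxyvitamin D [25(OH)D, nmol/L] against incident dementia, incident
stroke and brain-volume outcomes: a progressively adjusted observational
arm, pleiotropy-robust linear Mendelian randomization (MR), and a nonlinear
MR based on instrument-free stratification with fractional-polynomial
meta-regression, feeding a potential-impact-fraction calculation.  Because
the individual-level data such analyses run on are access-restricted, the
package ships a synthetic-cohort generator whose defaults encode the
statistical structure the analysis assumes; every estimator is exercised
and tested against that stated world.

## The synthetic world

`simulate.SimParams` freezes one stated world; all of it is configurable.

**Genetics.** 35 independent biallelic variants with effect-allele
frequencies uniform on [0.05, 0.5] (the MAF > 5% selection filter holds by
construction), genotypes Binomial(2, eaf) per variant (Hardy–Weinberg, no
LD).  One variant carries ~4× the typical weight, standing in for the
vitamin-D binding-protein (GC) locus; block labels allow leave-block-out
analyses.  The weighted GRS is calibrated so that it explains
`target_r2` = 2.8% of exposure variance — the instrument strength the
analysis assumes.  Calibration solves for a single weight scale factor
against the *clipped*-exposure model: conditional on draw month the
exposure is normal, clipping to the assay limits winsorizes it, and
Stein's lemma gives the GRS–exposure covariance as Var(GRS) × P(interior).
Without this correction the assay floor attenuates the realized R² by
about 6% of its value, enough to move the instrument-free residual
correlation (√(1−R²), the analytic identity the acceptance script checks)
off its third decimal.

**Exposure.** vitd = 50 + (GRS − E GRS) + season + 8·confounder + noise,
clipped to [10, 240] nmol/L (assay floor and top analysis category).  Mean
50 and SD 20 nmol/L are stand-ins — the source study never prints the
cohort distribution — chosen so the deficiency categories (<25, 25–50) are
well populated.  Season is a sinusoid over month of draw with amplitude
8 nmol/L peaking in August; the latent confounder is standard normal.

**Outcomes.** Dementia and stroke are exponential time-to-event outcomes
with independent exponential censoring and an administrative end of
follow-up at 10.9 y (the study's median).  The dementia log-hazard is
piecewise linear in the exposure with a knot at 50 nmol/L: slope
ln(0.35)/10 ≈ −0.105 per nmol/L below the knot and 0 above.  The anchor is
the study's stratified IVW estimate in the deficient range (OR 0.35 per
10 nmol/L); its fitted-curve contrast (OR 1.54 at 25 vs 50 nmol/L) implies
a ~6× gentler slope, and the two cannot both hold in a piecewise-linear
model — the steeper anchor is the one that gives the synthetic study
detectable signal at n ≈ 2×10⁵.  Baseline hazards 7.5×10⁻⁴ (dementia) and
1.2×10⁻³ (stroke) per person-year reproduce the study's case counts
(2399 and 3760 among 294,514 over 10.9 y) at the reference exposure;
because the hazard is strongly elevated in the deficient tail, the
marginal simulated dementia incidence is ~4–5%, not the <1% of the source
cohort.  Stroke has zero causal slope but shares the confounder
(0.4 log-hazard per SD), giving a confounded, non-causal association.
Brain volumes depend on age, sex and the *square* of the confounder with
no causal exposure term, which induces a U-shaped observational
association with 25(OH)D through the confounder channel only.
Kinship weights are 1 for ~90% of participants and uniform on (0.5, 1)
for the rest.

What a green test on this world does **not** establish: robustness to LD
between instruments, population stratification, imputation dosage
uncertainty, non-proportional hazards, or assay measurement error — none
of which are simulated.

## Observational arm

Linear models for brain volumes (white-matter hyperintensity volume is
log-transformed first) and Cox models (Efron ties, lifelines) for dementia
and stroke, all weighted by (1 − kinship coefficient) and adjusted along a
nested ladder: basic (age, sex, centre, ethnicity, month) →
socioeconomic → lifestyle → sun behaviour → illness.  The exposure enters
per 10 nmol/L; nonlinearity is tested by a quadratic exposure term, and
Cox fits attach a Schoenfeld-residual proportional-hazards p-value.
Categorical analyses use the conventional bins (<25, 25–50, 50–75, 75–100,
100–125, 125–240 nmol/L) with 50–74.9 as reference; the pipeline default
merges the top bins (75–100–240 → 100–240) because the synthetic exposure
has essentially no mass above 125 nmol/L.  Interaction tests are
likelihood-ratio tests on exposure×modifier products (age and BMI
continuous, sex and ethnicity categorical), with three-way products on
top of all pairwise terms.  Pre-fit filters mirror the study's cleaning:
exposures outside the reportable limits set missing, brain volumes beyond
±3 SD excluded, prevalent cases dropped.

## Linear MR

Per-variant Wald ratios β_Y/β_X with delta-method SE se_Y/|β_X| are
combined by: random-effects IVW (multiplicative SE inflation
max(1, √(Q/(J−1))) — floored at 1 so underdispersion never produces
super-precision); MR-Egger (weighted regression with intercept, exposure
betas oriented positive, t-based inference with dispersion floored at 1);
the weighted median (linear interpolation of the weight-standardised
cumulative distribution of sorted ratios; parametric-bootstrap SE, 1,000
seeded replicates); and the weighted mode (weighted Gaussian-kernel
density over ratios, modified-Silverman bandwidth × φ with φ = 1,
bootstrap SE).  MR-PRESSO simulates the null distribution of the
leave-one-out residual sum of squares (default 1,000 draws, seeded),
Bonferroni-flags per-variant outliers at 0.05, reports the IVW after their
removal, and compares the induced distortion against removals of random
subsets of the same size.

The stratified (one-sample) analysis re-estimates per-variant
exposure (OLS, Frisch–Waugh residualisation) and outcome (logistic; Cox
available by config — the study's "odds" language motivates logistic as
default) associations within strata of instrument-free exposure
(<25, 25–50, 50–75, ≥75 nmol/L) and applies every estimator per stratum.
Estimates are per nmol/L internally and reported as OR per 10 nmol/L.

## Nonlinear MR

The instrument-free exposure is the residual from regressing 25(OH)D on
the GRS, re-centred by adding back the sample mean so thresholds stay on
the measured nmol/L scale (re-centring preserves ranks and hence the
stratification; it only relabels the strata in familiar units).  The
cohort is cut into K = 40 equal-size quantile strata (stable ties).
Within each stratum the localized average causal effect is
LACE = β_GY/β_GX (logistic outcome slope over linear exposure slope on
the GRS, covariate-adjusted), se = se(β_GY)/|β_GX| — an estimate of the
local derivative of the causal log-odds dose–response.  The assumption of
a constant instrument–exposure association is checked per stratum:
β_GX outside the 99.7% prediction band (±3 se) around the
precision-weighted pooled slope flags the stratum.  On simulated data the
extreme strata are the ones flagged, because clipping at the assay floor
attenuates the genetic effect there — the same edge-strata pattern the
source analysis reported; flagged strata are excluded from the primary
fit by default (configurable).

The causal effect function is modelled as a fractional polynomial
h(x) = Σ_d θ_d f_{p_d}(x), powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3}
(f_0 = ln x; repeated powers use the ln-augmented convention), and each
stratum contributes LACE_k ≈ h′(mean_k) with weight 1/se².  Degree 1
scans all 8 powers, degree 2 all 36 pairs; the fit is weighted least
squares, model choice by maximal weighted Gaussian likelihood, and
degree 2 is retained only if it beats the best degree 1 at p < 0.05
(χ², 2 df).  Nonlinearity tests: best degree-1 vs the linear (power-1,
constant-derivative) model (χ², 1 df); the Wald p of the slope in a
precision-weighted meta-regression of LACE on mean exposure (a linear
trend in the derivative ≡ quadratic effect function); and Cochran's Q.
The coefficient covariance is (XᵀWX)⁻¹ with the LACE SEs taken as known
(fixed-effect meta-regression); possible residual overdispersion between
strata is not propagated.

OR(x) = exp(h(x) − h(reference)), reference 50 nmol/L, is exactly 1 at the
reference.  Confidence bands come from 10,000 seeded multivariate-normal
draws of θ (percentile method) rather than the delta method: the bands are
honest for the exponentiated contrast and inherit OR(reference) = 1
exactly.  The basis is evaluated down to the 10 nmol/L assay floor, which
also guards the negative/log powers against non-positive arguments.

A structural caveat found while validating against a hard-threshold world:
when the true derivative is a step (constant below the knot, zero above)
and the below-knot signal is strong, no member of the fractional-
polynomial family is flat above the knot while steep below it, so the
fitted curve keeps declining past the knot and the OR at 75 vs 50 nmol/L
can exclude 1 even though the generating effect there is null.  The same
stratified analysis applied to that world also shows the 25–50 stratum at
least as significant as the <25 stratum — with a uniform slope below the
knot, the larger stratum simply carries ~3× the events.  Both behaviours
are properties of the method on that world, not implementation defects,
and the corresponding acceptance-suite assertions are left failing rather
than relaxed.

## Potential impact fraction

PIF = (Σ RR(x_i) − Σ RR(x_i′)) / Σ RR(x_i) with x′ = max(x, threshold)
("shift-to-threshold" counterfactual) and RR read off the fitted curve as
the OR against the threshold — a rare-outcome approximation that is exact
in the source cohort (incidence < 1%) and only approximate in the
higher-incidence synthetic world.  The CI jointly bootstraps individuals
and redraws θ from its covariance each replicate (percentile method,
1,000 seeded replicates).  PIF is monotone in the threshold whenever RR
is non-increasing below it, and invariant to duplicating the population.

## Numerical conventions

* All randomness flows through `numpy.random.default_rng` seeded per
  stage; equal configs give byte-identical artifacts (gzip streams are
  written with zeroed timestamps).
* Quantile strata split by stable argsort; sizes differ by at most 1.
* Missing dosages are mean-imputed as 2·eaf before scoring.
* Palindromic (A/T, C/G) variants are dropped when the exposure EAF lies
  in [0.40, 0.60]; outside that window orientation is resolved by
  minor/major-allele agreement of the two frequencies.
* Logistic fits use Newton iterations capped at 50; strata with zero
  events, zero GRS variance or zero dosage variance raise immediately
  rather than returning degenerate estimates.
* The F-statistic uses the exact simple-regression identity
  F = R²(n−2)/(1−R²); it is reported as a diagnostic, not asserted
  against the study's printed value, whose R²/n rounding is unknown.
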
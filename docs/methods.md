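# Methods

This note documents the models, defaults and numerical choices behind
`wakecomp`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Compositional geometry

A wake-time composition is a strictly positive triple
**x** = (SB, LPA, MVPA) closed to a constant κ (724 minutes for the
analysis window — roughly a 12-hour waking day — or 1/100 for proportions).
Closure is the only admissible scaling: all analyses are invariant to κ.

Ilr coordinates come from a sequential binary partition (SBP). The sign
matrix `[[+1, −1, −1], [0, +1, −1]]` yields the canonical contrast matrix
with rows √(2/3)·(1, −½, −½) and √(½)·(0, 1, −1); the first ("pivot")
coordinate carries all relative information about SB versus the geometric
mean of the two activity intensities, the second LPA versus MVPA. Rotated
bases isolating LPA or MVPA are generated by permuting labels through the
same constructor, never hand-coded; the three bases differ by an orthogonal
rotation, so fitted values, residuals and R² of any linear model on the
coordinates are identical across pivots and only coefficient labels change.
A useful internal identity (used as a test): the three pivot-first
coefficients sum to zero.

Zeros make the ilr undefined. The pipeline treats a zero behavior as a hard
error after imputation — the screening step (`check_zeros`) must come back
empty — and a multiplicative-replacement utility is provided separately for
exploratory use only, never applied silently.

The group-contrast display (`logratio_diff`) uses the centered convention:
close both compositions, take part-wise ln(group/overall), subtract the mean
of the three log-ratios. The centering makes the three bars sum to zero;
other conventions differ by a constant offset, so plotted magnitudes should
be compared only within one convention.

## Accelerometry

Counts are classified per epoch with the Evenson children's cut points,
stored against their 15-second reference epoch (SB ≤ 25, LPA 26–573,
MVPA ≥ 574 counts) and rescaled linearly with floor rounding to the
recording epoch — 3-second epochs give ≤ 5 / 6–114 / ≥ 115. Thresholds live
in configuration, not code. Classification uses the vertical-axis counts
only, and interval membership is closed on the left cut ([0, sb_max] is
sedentary), both documented conventions rather than published constants.

Wear/non-wear follows the diary mask supplied with the data (the cohort
design used parent diaries); a 20-minute consecutive-zero heuristic
(`detect_nonwear`) is available as an explicit opt-in. A day is valid with
≥ 600 minutes (10 h) of wear; a participant needs ≥ 3 valid days, otherwise
they are excluded (an accounted value, not an error). Per-behavior minutes
always sum to wear minutes exactly, by bookkeeping.

## Synthetic cohort

The generator's defaults are the study conditions the pipeline targets:

* n = 589 children; P(rDCD) = 0.489.
* Compositions: logistic-normal. Draws are bivariate normal in canonical ilr
  space around ilr of the mean composition (62.33, 27.75, 9.92)% of a
  724-minute window, mapped back through the inverse ilr. The 2×2 ilr
  covariance is moment-matched so the percent-space part SDs hit
  (5.16, 3.50, 2.65): `calibrate_ilr_dispersion` pushes a fixed 20,000-point
  standard-normal quasi-sample through the map and solves for
  (log sd₁, log sd₂, atanh ρ) by least squares — deterministic, cached, and
  accurate to well under 0.1 percentage points on its own sample.
* Group differences in composition default to zero (a finding the pipeline
  is designed to reproduce); a config switch introduces shifts for power
  studies.
* Covariates: age ~ N(4.94, 0.59²); 57.4% male; income multinomial over
  four brackets (13.2/30.2/31.2/25.3%); 81.0% White; a BMI score
  ~ N(56.07, 27.14²). The BMI variable is named `bmi_score` deliberately:
  the source scale is ambiguous between a z-score label and percentile-like
  values, and the generator reproduces the printed moments without resolving
  the ambiguity.
* Outcomes: internalizing and externalizing t-scores are linear in the two
  canonical ilr coordinates and covariates plus Gaussian noise. Effects
  multiply centered predictors, so the marginal mean is exactly the target
  (48.02 internalizing, 45.55 externalizing — the t-score scale has
  population mean 50, SD 10; these cohort means sit slightly below).
  Default true ilr effects are (−0.26, +3.40637) for internalizing and
  (−5.24, +1.77824) for externalizing; the first coordinates are the
  headline pivot effects, and the second coordinates are derived so the
  three pivot rotations produce the full published-style coefficient
  pattern (+3.08/−2.82 internalizing, +4.16/+1.08 externalizing) — the
  sum-to-zero identity across pivots pins them given the first coordinate.
  rDCD adds +3.08 / +4.03 points. Noise SDs are solved so marginal SDs are
  9.82 / 9.27. Residuals across the two outcomes share a correlation of 0.5
  — an assumption (the outcome correlation is not an observed quantity),
  exposed in config.
* Missingness: block-wise MAR. All accelerometry columns drop together at
  rate 0.127 and both outcomes together at 0.012, with a ×2 odds weight for
  the lowest income bracket, renormalized so the marginal rate is exact.
* Epoch streams: `emit_epoch_streams` draws counts uniformly inside each
  behavior's cut-point band so that classify → summarize recovers the
  planted daily minutes within one epoch, giving the accelerometry stage a
  round-trip oracle.

All randomness derives from one integer seed via `SeedSequence.spawn`, so
stages have independent reproducible streams.

What the generator does **not** emulate: diurnal activity patterns and bout
structure, household clustering, longitudinal waves, non-Gaussian outcome
tails, and any group difference in compositions (by default). Passing tests
therefore certify the statistical machinery under a correctly specified
logistic-normal/linear world, not the behavior of the pipeline on real
accelerometer data.

## Imputation

`ChainedImputer` is MICE-style: every incomplete variable is regressed on
all others, 10 cycles, 5 completed datasets, one selected uniformly at
random (the compositional stack downstream operates on a single completed
dataset; pooling across imputations by Rubin's rules is an explicit
non-goal). Draws are proper: continuous targets get coefficients perturbed
by their estimated covariance plus residual noise; binary targets are
Bernoulli draws from a logistic fit (with a marginal-rate fallback under
separation); the four-level income bracket is a multinomial-logit draw.
Behavior minutes are imputed on the ilr scale by default — impute the two
coordinates, back-transform, rescale by the participant's wear time — which
guarantees positive minutes; raw-scale imputation is available and can, in
principle, produce negatives that the closure stage would then reject.
Observed cells are never modified, and every imputed cell is flagged.

Because the default generator gives the composition only weak predictors,
the conditional distribution of an imputed ilr coordinate is close to its
marginal; a proper stochastic draw then differs from the truth by roughly
the difference of two independent draws (MAE ≈ √2·√(2/π) ≈ 1.13 marginal
SDs), while remaining unbiased for means. The suite checks unbiasedness at
a reduced scale (20 replicates of n = 1,500) chosen to keep the run short;
the property is scale-free.

## Inference

**MANCOVA.** The group effect on the two ilr coordinates, adjusting for
age, sex, income (three indicators against the lowest bracket) and
ethnicity (binary), is tested with Wilks' Λ = det(E)/det(E + H), where E is
the full-model error SSCP and H the extra error of the no-group model. With
p = 2 responses and one hypothesis degree of freedom the F transform is
exact: F = ((vₑ−1)/2)(1−Λ)/Λ on (2, vₑ−1) df, vₑ = n − rank(design). The
covariate coding gives rank 8, hence df (2, 580) at n = 589 — the coding
was chosen because it is the one that reproduces that error df. The
statsmodels MANOVA is used as an independent cross-check in tests, never as
the implementation.

**Compositional regression.** OLS of each outcome on (1, ilr1, ilr2,
covariates) under each of the three pivot bases, adjusting for rDCD status,
age, sex, income, ethnicity and the BMI score. Two-sided p-values at
α = 0.05, no multiplicity adjustment (a deliberate mirroring of common
practice in this literature; six behavior-outcome tests are reported).

**Influence and robustness.** Cook's distance is computed in closed form,
D = (standardized residual²/p)·h/(1−h), flagged above 4/n; perfect-leverage
points are reported as infinite influence. When any observation is flagged
(or on request) the model is refitted with an MM estimator: a 50%-breakdown
S-estimate (bisquare ρ, c = 1.5476, 50 elemental starts with short IRLS
refinement) provides the scale and starting point, then IRLS with bisquare
ψ at c = 4.685 (95% Gaussian efficiency) iterates at fixed scale until the
coefficient change falls below 1e-8 (200 iterations max; non-convergence
raises, carrying the last iterate). Standard errors use the usual MM
sandwich s²·[n/(n−p)]·mean(ψ²)/mean(ψ′)²·(XᵀX)⁻¹. Noiseless designs are
detected (S-scale below 1e-10 of the response scale) and returned as exact
least-squares fits. Both OLS and robust fits are reported side by side; the
robust fit is the headline when screening fired, since reported effect
estimates in this design tradition follow the robust refit. The estimator
reproduces R's MASS `rlm(method="MM")` to ~3e-4 on a frozen contaminated
fixture; on clean Gaussian data it differs from OLS by the theoretically
expected ≈ 0.23 SE per coefficient (efficiency 95%), not less.

**Isotemporal substitution.** The reference composition defaults to the
sample compositional (geometric) mean closed to 724 minutes — the
convention of standard time-use substitution software; any feasible base
can be configured. For each ordered behavior pair and Δ ∈ {5, 10, 15, 20,
25} minutes, the new composition moves Δ from one part to the other
(exactly, third part untouched), and the predicted outcome change is
bᵀ·(ilr(new) − ilr(base)) over the two ilr coefficients — covariates cancel
in the difference, so fixing them at any reference is immaterial. The 95%
CI is the normal-theory interval on this linear form (the delta method is
exact here because the predictor is linear in the coefficients), using the
headline fit's coefficient covariance. A coefficient can be individually
significant while no single reallocation's CI excludes zero — the grid's
contrasts are different linear forms with their own variances — and the
pipeline exhibits both patterns on synthetic data depending on seed.
Reallocation is antisymmetric only to first order: change(A→B, Δ) ≈
−change(B→A, Δ) with equality in the Δ→0 limit, because the ilr difference
is nonlinear in Δ.

## Numerical choices

* Closure and ilr round-trips are required to 1e-9 relative; pivot-rotation
  invariance of fitted values to 1e-10; Cook's distance against the
  leave-one-out oracle to 1e-8. All are far inside double precision for
  D = 3.
* Classification boundaries are closed on the left cut; cut-point rescaling
  floors after linear scaling.
* The inverse ilr subtracts the row maximum before exponentiating
  (overflow-safe softmax form).
* M-scale equations are solved by bisection in log-space to a 1e-12
  relative bracket.
* CSVs are written with a fixed `%.10g` float format, and the orchestrator
  reloads each stage's CSV before continuing, so a single `run-all` is
  byte-identical to a stagewise restart at the same seed.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to keep the default suite fast
while leaving Monte-Carlo error well inside the asserted bounds: type-I
error of MANCOVA and regression at n = 200 over 1,000 replicates (binomial
SE ≈ 0.7 points against a ±2-point band); recovery of the planted −5.24
pivot effect at n = 589 over 500 replicates (MC SE of the mean ≈ 0.11
against a ±0.3 band); generator calibration at n = 5,000; imputation
unbiasedness at n = 1,500 over 20 replicates.

## Known limitations

* Only one-to-one pairwise reallocations are implemented (no
  one-vs-remaining substitutions).
* The MANCOVA exact F covers the (p = 2, one hypothesis df) case the
  pipeline uses; other shapes would need Rao's approximation, which is not
  wired in.
* Ternary-density plotting is out of scope; the grid plot is the only
  figure.
* Device-file parsing (.gt3x/.agd), sleep, and bout/pattern metrics are out
  of scope; epoch input is a long CSV.
* Single stochastic-regression imputation understates between-imputation
  variance relative to full multiple imputation; standard errors downstream
  inherit that optimism. This mirrors the analysis tradition the pipeline
  implements and is flagged rather than fixed.
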
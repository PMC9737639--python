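# Methods

## Scope and model

`ssbtax` simulates the population-health effect of an ad-valorem excise tax
on sugar-sweetened beverages (SSBs) through a four-stage pipeline run on an
individual-level population table:

1. **Price stage.** Each taxed category's retail price rises by
   `100 · tax_rate · pass_through` percent. Pass-through below 1 models
   partial absorption of the tax by manufacturers; the sensitivity runner
   re-evaluates every scenario at alternative pass-through rates (default
   comparison: 80% vs the 100% reference).
2. **Demand stage.** Demand responds through a K×K elasticity matrix
   `ε` (diagonal own-price, off-diagonal cross-price). The default response
   is linear first order, `%Δq_j = Σ_i ε_ji %Δp_i`, which is the standard
   reading of an elasticity as the percent demand change per percent price
   change. Because demand models are sometimes applied multiplicatively, a
   log form `q' = q·Π(1+Δp_i)^{ε_ji}` is available behind `form="log"`; the
   two agree to first order in `Δp`. The same percentage change applies to
   every individual regardless of stratum — absolute heterogeneity enters
   only through baseline consumption levels. Shifted volumes are floored
   at zero.
3. **Energy-balance stage.** Net daily energy change per person is the
   density-weighted sum of volume changes. The body-weight response uses
   the simplified steady-state rule — 100 kJ/day of sustained intake change
   per kg of steady-state weight change (kcal→kJ fixed at 4.184) — with an
   exponential time course `Δw(t) = Δw_ss(1 − e^{−t/τ})`. `τ` is calibrated
   so the configured attainment fraction (default 0.95) is reached exactly
   at the evaluation horizon (default 3 years). The literature's two
   informal anchors (half the change at ~1 year, 95% at ~3 years) are
   mutually inconsistent for a single exponential; the applied contrast is
   a two-stationary-state comparison anchored to 95%-at-3-years only, so
   that anchor is the one the calibration honours. Height is constant, so
   `ΔBMI = Δw/h²` exactly. Post-tax weight is floored at a physiologic
   minimum (default 30 kg, counted and reported, never raising an
   individual who starts below it). Energy expenditure and physical
   activity are outside the model.
4. **Outcome stage.** BMI classes use the standard cut-offs (overweight
   25 ≤ BMI < 30, obesity ≥ 30). Prevalence is the survey-weight share of a
   class; the tax effect is the *relative* change in prevalence
   (percent of baseline, not percentage points) plus the implied
   expansion-weighted person-count change, per sex × age stratum, per sex,
   per age group and overall. By default the **whole** population is
   classified on both sides of the tax, so individuals may enter a class
   from below as weight rises; the one-sided variant that follows only the
   baseline members of each class is available via
   `restrict_to_baseline_class=True`. The default is the behaviour
   consistent with overweight prevalence being able to rise, which the
   restricted reading cannot produce.

Confidence intervals are nonparametric percentile bootstrap over
individuals (default B = 1000), resampled within each reported stratum with
one shared resample feeding every statistic of that stratum; seeds are
derived from the master seed by a fixed offset so each stage is
independently reproducible.

## Synthetic population generator

The generator emulates a merged consumption + anthropometry survey of
adults (20+). Its defaults are calibrated to the published Brazilian
baseline profile and are the fixed study conditions of the test suite:

* **Anchors (mL/person/day):** SSB overall 176 (≈67 kcal), soft drinks 65%
  of SSB volume (other sugary drinks 20%, sweetened milk drinks 10%,
  sports/energy 5% — the latter two are splits of the printed remainder,
  not published values); ages 20–29 at 268.6 down to 105.5 at 70+; men 208
  vs women 153; non-sweetened caloric beverages (milk 6%, fruit juice
  36.7%, coffee/tea 57.3% of volume) 576 overall (≈153 kcal). Water is
  calorie-free at a flat 500 mL/day.
* **Derived male share.** The three printed sex/overall SSB means are
  jointly consistent only if the male population share is 23/55 ≈ 0.418;
  the generator uses that derived share so all three anchors hold
  simultaneously in expectation.
* **Age gradient.** Only the two extreme age means are published. The
  intermediate strata follow a monotone geometric decline
  `μ_a = c + b·ρ^a` through both anchors, with `ρ` solved (Brent) so the
  age-share-weighted overall mean equals 176 exactly. Age shares
  (0.23/0.22/0.19/0.16/0.12/0.08 from 20–29 to 70+) approximate the adult
  age structure and are config inputs.
* **Non-sweetened age ramp.** Substitute-beverage consumption rises with
  age (400→740 mL/day raw ramp, rescaled so the overall mean is exactly
  576). The ramp steepness was chosen once, together with the illustrative
  elasticities, so that ages 20–29 are the only net calorie reducers — the
  qualitative regime of the source setting — and is not tuned thereafter.
* **Energy densities (kcal/mL):** soda 0.382, sweetened milk drinks 0.60,
  sports/energy 0.25, other sugary 0.30, milk 0.60, juice 0.45, coffee/tea
  0.1125 (lightly sugared), water 0. Chosen so the volume targets imply the
  published energy targets (67 and 153 kcal/day); each is overridable.
* **Consumption distribution:** zero-inflated gamma per category
  (zero-probability per category, e.g. 0.40 for soda, 0.90 for
  sports/energy; gamma shape 1.2, CV ≈ 0.91 among consumers), with the
  consumer mean inflated so the stratum mean equals its target.
* **Anthropometry:** height normal per sex (men 1.73 ± 0.07 m, women
  1.61 ± 0.065 m, floored at 1.30); BMI lognormal per sex with (μ, σ)
  solved in closed form from target overweight/obesity prevalences
  (defaults: men 36%/21.8%, women 33%/29.5% — assumptions in the range of
  recent national health-survey estimates, not published values of the
  source study); weight = BMI·h².
* **Survey weights:** lognormal (σ = 0.3) heterogeneity normalized to a
  total expansion of 159 million adults; weights are independent of all
  other variables, so they exercise the weighted-estimator code paths
  without biasing means.
* **Consumption–BMI correlation:** zero by default (the demand response is
  applied independently of baseline BMI); a rank-correlation knob
  (`bmi_consumption_rho`) exists for experimentation.

**What the generator does not emulate:** the complex multistage sample
design of the real surveys (strata/PSU clustering and calibration weights
— the bootstrap here treats individuals as i.i.d.), measurement error of
24-h recalls and self-reported anthropometry, within-person day-to-day
intake variation, income gradients in demand, and any correlation between
beverage choices. Passing the calibration tests therefore shows the
pipeline arithmetic and the calibration machinery are correct, not that
real-survey point estimates would be reproduced.

## Elasticities

The demand study underlying the original analysis is not redistributable,
so the shipped matrix is **illustrative**: own-price −1.0 for the four SSB
classes, no cross-effects among them, and positive cross-price terms from
the taxed classes to milk (summing 1.10), fruit juice (0.70), coffee/tea
(0.55) and water (0.30). With these values and the default baselines, a
20% fully-passed tax yields an overall mean energy change of about
+8 kcal/person/day and mean ΔBMI ≈ +0.12 kg/m² — the sign/magnitude regime
of the setting it illustrates — with the reduction concentrated in ages
20–29. Quantitative replication requires supplying the estimated matrix
(`ElasticityMatrix.from_csv`/`from_yaml`).

## Numerical choices and degenerate inputs

* Zero tax or zero pass-through is an exact identity end to end (no
  floating-point drift is introduced anywhere on the null path).
* Under the linear form, per-individual ΔE is exactly proportional to
  pass-through (the 80% run equals 0.8× the 100% run).
* Positive own-price elasticities warn but do not error; mismatched
  category sets, unknown taxed categories, nonpositive heights, all-zero
  weights, and empty populations raise with the offending names.
* A stratum with zero baseline prevalence reports a missing relative
  change with a warning rather than dividing by zero.
* Report rendering refuses to overwrite a non-empty output directory
  unless forced.

## Problem sizes

The test suite and the acceptance script use n = 50,000 individuals for
calibration and pattern checks (the package's default study scale),
n = 2,000–36,000 for law-of-large-numbers and bootstrap-width checks, and
B = 200–1000 bootstrap replicates depending on whether a width or only
reproducibility is being assessed. All randomness flows from explicit
seeds; identical (config, seed) pairs give bit-identical populations and
results.

## Known limitations

Elasticities are uniform across sex, age and income; the energy-balance
rule is a single-compartment simplification (no fat/lean partitioning or
adaptive thermogenesis, no sex-specific equations); consumption changes are
sustained and instantaneous at t=0; revenue, GDP and employment effects are
out of scope.
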
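# Methods

## Scope and assumptions

The package estimates what national firearm- or pesticide-restriction
policies implemented in 2020 would do to forecast suicide mortality by 2030,
at country, subregion and region level. It is an ecological model: effects
are applied at the population level through rate ratios, and nothing is
inferred about individuals. Core assumptions, all inherited from the study
design the pipeline implements:

* the pre-2020 trend of each country-sex age-standardized rate (ASR)
  series, extrapolated, is the no-intervention baseline;
* the sex-specific proportions of firearm- and pesticide-involved suicides
  are frozen at their reference year (2019) across the whole horizon;
* a single published rate-ratio schedule per means applies to every
  restricted country, both sexes, all ages — the `RR_other` component
  applied to the non-targeted rate is what represents means substitution;
* the percentage change in the ASR mirrors the percentage change in every
  age-specific rate, which converts rate trajectories to death counts using
  base-year age-specific rates and projected populations.

## Trend description (joinpoint)

Continuous piecewise-linear least squares on the natural rate scale, with
breakpoints restricted to observed interior integer years and at least 3
observations per segment. The number of joinpoints (0–3 by default) is
chosen by BIC with `k = 2 + 2·(number of joinpoints)` parameters — each
joinpoint is charged for a location and a slope change — and ties go to
fewer joinpoints; the SSE is floored at 1e-12 so that zero-residual series
select the simplest model deterministically. The fit is descriptive: it
supplies the final-segment slope used to vet forecasts, and no inferential
claims (APC confidence intervals, permutation tests) are made. Fitting on
the natural rather than the log scale matches the forecast models, which
extrapolate rates directly.

## Forecasting

Candidate models per series (2000–2019, n = 20):

* **linear** — OLS on calendar year with classical 95% prediction intervals;
* **arima** — ARIMA(p,d,q), p,q ∈ {0,1,2}, d ∈ {0,1}, selected by AICc;
  a constant is included for d = 0 and a linear drift for d = 1, so trended
  series extrapolate their trend. Twenty observations cannot support a
  larger grid;
* **lowess_arima** — LOWESS (span 0.2, the locality that tracks roughly a
  4-year window at n = 20) smooths the series first and the auto-ARIMA is
  fit to the smoothed values. Prediction intervals come from the ARIMA
  stage only; smoothing uncertainty is ignored, which understates interval
  width slightly.

"The extrapolation should continue the recent trend" is operationalized as
a quantitative vetting rule: the OLS slope of the forecast's first five
years must not oppose the final joinpoint segment's slope in sign, and must
agree in magnitude within `max(0.5·|segment slope|, 0.05 per 100,000/yr)`.
Both cutoffs are tunable; 0.05 per 100,000/yr is the scale below which two
flat-ish trends are visually indistinguishable on these series. Linear is
tried first, then ARIMA; the first candidate passing wins, and if both fail
the hybrid is used unconditionally, mirroring its role as the fallback for
series whose global fits do not track the recent segment.

Numerical choices:

* a series whose linear fit is exact (max |residual| < 1e-8 relative) is
  extrapolated in closed form by *all three* methods: ARIMA maximum
  likelihood is ill-conditioned as the innovation variance tends to zero,
  while the limit forecast is the line itself;
* an ARIMA fit that fails outright (non-convergence, non-invertibility)
  falls back to the linear model with a logged warning;
* negative point forecasts (and negative lower bounds) are floored at zero
  and flagged per year; flags are what the eligibility rule and the deaths
  accounting consult, the raw values are preserved.

## Scenario eligibility and counterfactual algebra

Screening rules, applied in order per country: (1) 2019 both-sexes rate
below 3 per 100,000 → not eligible (the both-sexes rate is the
population-weighted combination of the two sex-specific ASRs — the rule's
sex handling was a genuinely open choice and this is the recorded one);
(2) no means profile → not eligible (absence is explicit, never coerced to
zero proportions); (3) a means qualifies if its proportion meets the
threshold for at least one sex — a granted restriction applies to both
sexes, since national policy is not sex-specific; if both means qualify,
the one with the larger maximum sex-specific proportion wins (no such case
arises in the bundled topology; a deterministic rule is still required);
(4) any raw-negative baseline forecast → not eligible, because scaling a
floored-to-zero baseline is undefined.

For restricted countries, each post-intervention year t maps to
k = t − 2020 (2021 → k = 1), the baseline is decomposed with the frozen
proportion, and the schedule's (RR_target(k), RR_other(k)) are applied.
Schedules shorter than the horizon carry their last entry forward — 10-year
horizons can exceed published follow-up. Non-restricted countries carry
their baseline forecasts unchanged into aggregation, so subregional and
regional rates always reflect the full membership.

## Deaths and aggregation

`deaths(t) = Σ_a m_a(2019) · (ASR(t)/ASR(2019)) · N_a(t) / 100,000`, which
reduces to `ASR(t) · K(c,s,t)` with a precomputed conversion factor K; the
factorization is exact and is what makes the Monte Carlo loop cheap. The
base year is 2019, the last observed year. A zero base-year ASR with a
nonzero forecast is an error, not a silent zero. Subregional and regional
rates are weighted means with year- and sex-specific total populations as
weights (whether aggregation weights should be sex-specific was open;
sex-specific is the default and the weights argument is a plain population
table, so total-population weighting is a one-line substitution).

## Uncertainty

1000 Monte Carlo draws; 95% uncertainty intervals are the 2.5th/97.5th
percentiles; the reported point estimate is always the deterministic run,
never the draw mean. Distribution families are conventional choices for
rate and ratio parameters, recorded here because no family is dictated by
the method itself:

* forecast rates: normal, mean = point forecast, sd = (hi − lo)/3.92,
  truncated at zero — the per-draw analogue of the zero imputation;
* rate ratios: lognormal, median = RR, log-sd = (ln hi − ln lo)/3.92. One
  draw per (means, k, component) is shared across all countries under that
  restriction within a draw: the RR is a single literature estimate whose
  error is systematic, not per-country.

Within a draw, the baseline arm and the counterfactual arm of a restricted
country use *independent* rate draws, so the avoided-deaths interval
reflects uncertainty in both trajectories and straddles zero under the null
(all RRs = 1) while the point estimate is exactly zero. Pairing the arms
would collapse the null interval to a point and understate uncertainty
everywhere else. Unrestricted countries contribute exactly zero avoided
deaths in every draw. Toggles exist for switching rate or RR uncertainty
off individually; both default on. A single master seed (default 20240716)
makes every interval bitwise reproducible.

## Synthetic data generator

Emulates the four real inputs with known ground truth: piecewise-linear
trends plus independent Gaussian noise truncated at zero on the rate scale
(default sd 0.1 per 100,000, matching the smoothness of modeled national
rate series); 18 five-year age bands with base-year age-specific rates
scaled so that their standard-population average equals the observed 2019
ASR exactly; constant exponential population growth per band; 10-year
synthetic RR schedules with CIs. Configurations implying negative mean
rates raise at generation time rather than clipping.

`paper_mimic_config` reproduces the qualitative topology of the Region of
the Americas inputs — 33 countries in 5 PAHO subregions, 9 countries below
the 3-per-100,000 screen, 4 without means profiles, 1 firearm + 4 pesticide
countries above the 0.40 threshold, 2 more entering at 0.20, and one
0.20-eligible country whose male forecast collapses below zero — with
synthetic levels and trends. What passing tests on this bundle show: the
algebraic chain is correct, model selection behaves sensibly on
piecewise-linear-plus-noise series, and eligibility logic matches the
documented rules. What they do not show: performance on real WHO series,
whose estimation-induced autocorrelation, revision artifacts and non-linear
trends the generator does not imitate; nor anything about the validity of
any particular published rate-ratio schedule, which the package treats as
user configuration.

## Problem sizes

Defaults throughout are the full study scale: 33 countries × 2 sexes × 20
observed years, 11 forecast years, 1000 Monte Carlo draws. The acceptance
script runs this complete configuration; the test suite uses the same
bundle via shared fixtures plus smaller constructed series where a property
is clearer at small n (e.g. 100 two-segment series for breakpoint recovery,
1000 random tables for the deaths oracle).

## Known limitations

* Frozen means proportions: trends in method mix over 2020–2030 are not
  modeled; a sensitivity switch would re-run with alternative profiles.
* Rate ratios are not sex- or age-specific, so sex differences in
  responsiveness to restriction are averaged away.
* Aggregated rate intervals in the deterministic tables are
  population-weighted country bounds, an approximation that ignores
  cross-country independence (Monte Carlo intervals are exact in-model for
  avoided deaths).
* The joinpoint BIC count (location + slope change per joinpoint) is one of
  several defensible conventions; a permutation-test selector is not
  implemented.
* No COVID-era shock adjustment: forecasts extrapolate pre-2020 data only.
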
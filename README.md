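# meanscast

Counterfactual modeling of national suicide **means-restriction** policies
(firearm access restrictions and bans on highly hazardous pesticides) on
age-standardized suicide mortality rates, for epidemiologists and public
mental-health analysts working with WHO-style country panels.

## The model

For each country *c* and sex *s*, the observed age-standardized suicide rate
(ASR, per 100,000, WHO standard population) over 2000–2019 is

1. **described** by joinpoint regression — a continuous piecewise-linear
   trend `E[y|t] = a + bt + Σ_j d_j (t − b_j)₊` with breakpoints selected by
   BIC over an exhaustive grid;
2. **forecast** to 2020–2030 by a linear model or an ARIMA(p,d,q) (AICc over
   p,q ≤ 2, d ≤ 1), whichever first extrapolates in line with the final
   joinpoint segment; when neither does, a LOWESS smoother (span 0.2) is
   applied and an ARIMA is fit to the smoothed values. Negative forecasts
   are floored at zero and flagged;
3. **restricted** under a scenario: a country implements a firearm or
   pesticide restriction in 2020 if that means accounts for ≥ threshold
   (0.40 in scenario 1, 0.20 in scenario 2) of its suicides for at least one
   sex, its 2019 both-sexes rate is ≥ 3 per 100,000, a means profile exists,
   and its baseline forecast never goes negative. The baseline rate is split
   by the frozen reference-year proportion *p* and multiplied by the
   year-indexed post-intervention rate ratios:

   `cf(t) = p·ASR(t)·RR_target(k) + (1−p)·ASR(t)·RR_other(k)`, `k = t − 2020`

   `RR_other` captures means substitution and may exceed 1;
4. **converted to deaths** via the mirroring assumption — the proportional
   ASR change applies to every age-specific rate:
   `deaths(t) = Σ_a m_a·(ASR(t)/ASR(2019))·N_a(t)/100,000`;
5. **aggregated** to PAHO subregions and the region by population-weighted
   means, and avoided deaths (counterfactual − baseline; negative = avoided)
   are given 95% uncertainty intervals from 1000 Monte Carlo draws
   (truncated-normal rates, lognormal rate ratios, 2.5th/97.5th percentiles).

Rate-ratio schedules are configuration, not constants: transcribe the
literature estimates you intend to use into the documented CSV layout
(`src/meanscast/data/rate_ratio_template.csv` shows the format with
synthetic placeholder values). A bundled synthetic-data generator produces
complete input bundles with known ground truth for testing and
demonstration.

## Worked example

```bash
python analysis/01_simulate.py            # synthetic 33-country bundle
python analysis/02_trends_and_forecasts.py
python analysis/03_scenarios.py
python analysis/04_uncertainty.py
```

prints, for the default bundle (seed 12345) and the generator's synthetic
rate-ratio schedules:

```
forecast 66 series; model counts by country: {'arima': 1, 'linear': 33, 'lowess_arima': 7}; 2 forecast-years floored at zero
joinpoint: 13/66 series show at least one trend change
scenario1 (threshold 0.40): 5 restricted (1 firearm, 4 pesticide): GUY, NIC, SLV, SUR, USA
  cumulative avoided deaths 2021-2030: male -77,084, female -12,010
scenario2 (threshold 0.20): 7 restricted (2 firearm, 5 pesticide): GUY, NIC, SLV, SUR, TTO, URY, USA
  cumulative avoided deaths 2021-2030: male -77,794, female -12,108
scenario1 Region male: -77,084 (95% UI -88,957, -62,545)
```

Reading: under the 0.40-threshold scenario one firearm and four pesticide
restrictions together avoid about 77,000 male and 12,000 female deaths by
suicide over 2021–2030 in this synthetic region; lowering the threshold to
0.20 adds two countries but little additional benefit, because the newly
restricted means account for a modest share of those countries' suicides.
Tables land in `results/` (aggregated rate trajectories, eligibility
decisions with reasons, yearly and cumulative avoided deaths with UIs).

The same pipeline is scriptable via the CLI: `meanscast simulate|forecast|
scenario|report` (see `meanscast --help`), with real data supplied in the
CSV schemas documented in `meanscast.panel_io`.

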
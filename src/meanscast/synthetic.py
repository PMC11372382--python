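"""Synthetic input bundles with known ground truth.

Generates internally consistent stand-ins for the four real inputs the
pipeline consumes -- a WHO-style rate panel, PAHO-style means profiles,
UN-style age-structured population projections, and rate-ratio schedules --
so every stage is testable without any download.  Nothing here imitates the
WHO's upstream estimation; the rates are piecewise-linear trends plus
truncated Gaussian noise on the rate scale.

Internal consistency guarantees:

* each country-sex series is a continuous piecewise-linear mean (known
  segments and breakpoints, recorded in the truth record) observed with
  independent N(0, sd^2) noise truncated at zero;
* base-year age-specific rates m_a are generated so that
  sum_a m_a * w_a = observed 2019 ASR exactly, for the bundled WHO standard
  weights w_a -- the deaths-mirroring algebra is then exact by construction;
* populations grow exponentially per age band at a constant country rate.

``paper_mimic_config`` reproduces the qualitative topology of the real
Region-of-the-Americas inputs -- 33 countries in 5 subregions, 9 countries
below the 3-per-100,000 screening rate in 2019, 4 countries with no means
profile, one firearm and four pesticide countries above the 0.40 proportion
threshold, two more countries entering at 0.20, and one 0.20-eligible
country whose male forecast goes negative -- without using any real
country's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import panel_io

YEARS_OBS = (2000, 2019)
YEARS_POP = (2000, 2030)


@dataclass
class SexTrend:
    """Piecewise-linear mean trend anchored at its 2019 level."""
    level_2019: float
    slopes: tuple[float, ...] = (0.0,)
    breakpoints: tuple[int, ...] = ()

    def means(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years, dtype=int)
        if len(self.slopes) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more slope than breakpoints")
        bounds = [years.min(), *self.breakpoints, years.max() + 1]
        slope_at = np.empty(len(years))
        for s, lo, hi in zip(self.slopes, bounds[:-1], bounds[1:]):
            slope_at[(years >= lo) & (years < hi)] = s
        # integrate forward then anchor at 2019
        mean = np.concatenate([[0.0], np.cumsum(slope_at[:-1])])
        anchor = mean[years == 2019][0]
        return mean - anchor + self.level_2019


@dataclass
class CountrySpec:
    code: str
    trends: dict[str, SexTrend]
    # (prop_firearm, prop_pesticide) per sex; None = no profile published
    props: dict[str, tuple[float, float]] | None
    population_total: float = 5e6
    growth_rate: float = 0.01


@dataclass
class SyntheticConfig:
    countries: list[CountrySpec]
    years: tuple[int, int] = YEARS_OBS
    noise_sd: float = 0.1
    ci_rel_halfwidth: float = 0.08  # reported CI half-width as fraction of the rate
    schedules: pd.DataFrame | None = None  # true RR schedules; default bundle below
    seed: int = 12345


def default_true_schedules() -> pd.DataFrame:
    """Plausible 10-year RR schedules used as synthetic ground truth.

    The firearm restriction reduces targeted-means mortality gradually with
    mild substitution; the pesticide ban acts faster and deeper.  These are
    generator truths, not estimates from any published evaluation.
    """
    rows = []
    for k in range(1, 11):
        rr_t = 0.90 - 0.035 * (k - 1)
        rr_o = 1.04 - 0.006 * (k - 1)
        rows.append(("firearm", k, rr_t, rr_t * 0.85, rr_t * 1.18,
                     rr_o, rr_o * 0.92, rr_o * 1.09))
    for k in range(1, 11):
        rr_t = 0.70 - 0.040 * (k - 1)
        rr_o = 1.06 - 0.012 * (k - 1)
        rows.append(("pesticide", k, rr_t, rr_t * 0.80, rr_t * 1.25,
                     rr_o, rr_o * 0.90, rr_o * 1.11))
    return panel_io.validate_schedule(pd.DataFrame(
        rows, columns=panel_io.SCHEDULE_COLUMNS))


@dataclass
class Bundle:
    panel: pd.DataFrame
    profiles: pd.DataFrame
    population: pd.DataFrame
    base_age_rates: pd.DataFrame
    base_asr: pd.DataFrame
    schedules: pd.DataFrame
    truth: dict


def _truncnorm_noise(means: np.ndarray, sd: float, rng) -> np.ndarray:
    if sd == 0:
        return means.copy()
    a = (0.0 - means) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=means, scale=sd, random_state=rng)


def generate_bundle(config: SyntheticConfig) -> Bundle:
    """Deterministically generate a full input bundle from ``config``."""
    rng = np.random.default_rng(config.seed)
    std = panel_io.load_standard_population()
    bands = list(std["age_group"])
    weights = std["weight"].to_numpy()
    years_obs = np.arange(config.years[0], config.years[1] + 1)
    years_pop = np.arange(YEARS_POP[0], YEARS_POP[1] + 1)

    panel_rows, prof_rows, pop_rows, age_rows, asr_rows = [], [], [], [], []
    truth_trends = {}
    for spec in config.countries:
        for sex in panel_io.SEXES:
            trend = spec.trends[sex]
            mean = trend.means(years_obs)
            if (mean < 0).any():
                bad = years_obs[mean < 0]
                raise ValueError(
                    f"trend for {spec.code}/{sex} implies negative mean rates at {list(bad)}"
                )
            asr = _truncnorm_noise(mean, config.noise_sd, rng)
            half = config.ci_rel_halfwidth * asr
            for y, v, h in zip(years_obs, asr, half):
                panel_rows.append({
                    "country": spec.code, "sex": sex, "year": int(y),
                    "asr": float(v),
                    "ci_low": float(max(v - h, 0.0)), "ci_high": float(v + h),
                })
            truth_trends[f"{spec.code}/{sex}"] = {
                "level_2019": trend.level_2019,
                "slopes": list(trend.slopes),
                "breakpoints": list(trend.breakpoints),
            }

            # base-year age-specific rates consistent with the observed 2019 ASR
            asr_2019 = float(asr[years_obs == 2019][0])
            shape = np.linspace(0.3, 2.4, len(bands))  # rates rise with age
            m_a = asr_2019 * shape / float(shape @ weights)
            for band, m in zip(bands, m_a):
                age_rows.append({"country": spec.code, "sex": sex,
                                 "age_group": band, "rate": float(m)})
            asr_rows.append({"country": spec.code, "sex": sex, "asr": asr_2019})

            base_by_band = 0.5 * spec.population_total * weights
            for y in years_pop:
                growth = (1 + spec.growth_rate) ** (int(y) - 2000)
                for band, base in zip(bands, base_by_band):
                    pop_rows.append({
                        "country": spec.code, "sex": sex, "age_group": band,
                        "year": int(y), "count": float(base * growth),
                    })

        if spec.props is not None:
            for sex, (pf, pp) in spec.props.items():
                prof_rows.append({
                    "country": spec.code, "sex": sex,
                    "prop_firearm": pf, "prop_pesticide": pp,
                    "reference_year": 2019,
                })

    panel = panel_io.validate_rate_panel(pd.DataFrame(panel_rows), window=config.years)
    profiles = panel_io.validate_means_profiles(
        pd.DataFrame(prof_rows, columns=[
            "country", "sex", "prop_firearm", "prop_pesticide", "reference_year"]))
    population = panel_io.validate_population(pd.DataFrame(pop_rows), age_bands=bands)
    schedules = config.schedules if config.schedules is not None else default_true_schedules()
    truth = {
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "trends": truth_trends,
        "schedules": schedules.to_dict(orient="list"),
    }
    return Bundle(
        panel=panel, profiles=profiles, population=population,
        base_age_rates=pd.DataFrame(age_rows), base_asr=pd.DataFrame(asr_rows),
        schedules=schedules, truth=truth,
    )


def generate_intervention_truth(
    forecasts: dict,
    profiles: pd.DataFrame,
    schedules: pd.DataFrame,
    eligibility: dict,
    config,
) -> pd.DataFrame:
    """Reference counterfactual rates via a direct scalar re-derivation.

    Applies the decomposition and rate-ratio algebra entry by entry with
    plain Python arithmetic, independently of the pipeline's implementation;
    used as the target in end-to-end recovery tests.
    """
    plook = {(r.country, r.sex): (r.prop_firearm, r.prop_pesticide)
             for r in profiles.itertuples()}
    sched = {(r.means, r.k): (r.rr_target, r.rr_other) for r in schedules.itertuples()}
    max_k = {m: max(k for mm, k in sched if mm == m) for m in {m for m, _ in sched}}
    rows = []
    for (country, sex), fc in sorted(forecasts.items()):
        dec = eligibility.get(country)
        restricted = dec is not None and dec.decision.startswith("restrict_")
        means = dec.decision.removeprefix("restrict_") if restricted else None
        for year, baseline in zip(fc.years, fc.point):
            k = int(year) - config.intervention_year
            if restricted and k >= 1:
                pf, pp = plook[(country, sex)]
                p = pf if means == "firearm" else pp
                rr_t, rr_o = sched[(means, min(k, max_k[means]))]
                cf = baseline * p * rr_t + baseline * (1 - p) * rr_o
            else:
                cf = float(baseline)
            rows.append({"country": country, "sex": sex, "year": int(year),
                         "counterfactual_true": float(cf)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the paper-mimic study configuration
# ---------------------------------------------------------------------------

# 2019 anchor levels (male, female) per 100,000 and per-sex trend slopes
_LOW_RATE = ["ATG", "BRB", "GRD", "HND", "JAM", "PAN", "PER", "VCT", "VEN"]
_NO_PROFILE = ["BHS", "BOL", "HTI", "LCA"]

_POP = {  # rough total-population scale, persons
    "USA": 330e6, "BRA": 210e6, "MEX": 125e6, "COL": 50e6, "ARG": 45e6,
    "CAN": 38e6, "PER": 33e6, "VEN": 28e6, "CHL": 19e6, "ECU": 17e6,
    "GTM": 17e6, "BOL": 12e6, "HTI": 11e6, "CUB": 11e6, "DOM": 11e6,
    "HND": 10e6, "PRY": 7e6, "NIC": 6.5e6, "SLV": 6.5e6, "CRI": 5e6,
    "PAN": 4.2e6, "URY": 3.5e6, "JAM": 3e6, "TTO": 1.4e6, "GUY": 0.8e6,
    "SUR": 0.6e6, "BLZ": 0.4e6, "BHS": 0.4e6, "BRB": 0.3e6, "LCA": 0.18e6,
    "VCT": 0.11e6, "GRD": 0.11e6, "ATG": 0.1e6,
}


def paper_mimic_config(seed: int = 12345, noise_sd: float = 0.1) -> SyntheticConfig:
    """A 33-country bundle with the study's eligibility topology built in."""
    rng = np.random.default_rng(seed + 1)  # country-level parameter jitter
    countries = []
    for code in sorted(_POP):
        pop = _POP[code]
        if code == "USA":
            trends = {"male": SexTrend(23.0, (0.35,)), "female": SexTrend(6.3, (0.12,))}
            props = {"male": (0.55, 0.01), "female": (0.31, 0.02)}
        elif code == "SLV":
            trends = {"male": SexTrend(11.0, (-0.15,)), "female": SexTrend(3.6, (-0.05,))}
            props = {"male": (0.10, 0.30), "female": (0.03, 0.42)}
        elif code == "GUY":
            trends = {"male": SexTrend(28.0, (0.25, -0.45), (2012,)),
                      "female": SexTrend(8.5, (-0.10,))}
            props = {"male": (0.05, 0.55), "female": (0.02, 0.60)}
        elif code == "NIC":
            trends = {"male": SexTrend(10.5, (-0.08,)), "female": SexTrend(3.4, (-0.03,))}
            props = {"male": (0.08, 0.45), "female": (0.02, 0.50)}
        elif code == "SUR":
            trends = {"male": SexTrend(33.0, (-0.20,)), "female": SexTrend(9.8, (-0.12,))}
            props = {"male": (0.10, 0.46), "female": (0.03, 0.52)}
        elif code == "URY":
            trends = {"male": SexTrend(31.0, (0.28,)), "female": SexTrend(7.6, (0.05,))}
            props = {"male": (0.32, 0.04), "female": (0.15, 0.06)}
        elif code == "TTO":
            trends = {"male": SexTrend(18.0, (-0.25,)), "female": SexTrend(4.6, (-0.08,))}
            props = {"male": (0.06, 0.22), "female": (0.04, 0.28)}
        elif code == "GTM":
            # meets the 20% threshold but its male forecast goes negative
            trends = {"male": SexTrend(4.4, (-0.45,)), "female": SexTrend(2.4, (0.0,))}
            props = {"male": (0.12, 0.25), "female": (0.05, 0.35)}
        elif code in _LOW_RATE:
            m19 = float(rng.uniform(2.2, 3.4))
            f19 = float(rng.uniform(0.6, 1.6))
            trends = {"male": SexTrend(m19, (float(rng.uniform(-0.04, 0.04)),)),
                      "female": SexTrend(f19, (float(rng.uniform(-0.02, 0.02)),))}
            props = {"male": (0.10, 0.08), "female": (0.05, 0.10)}
        elif code in _NO_PROFILE:
            m19 = float(rng.uniform(6.0, 12.0))
            f19 = float(rng.uniform(1.8, 3.5))
            trends = {"male": SexTrend(m19, (float(rng.uniform(-0.10, 0.15)),)),
                      "female": SexTrend(f19, (float(rng.uniform(-0.04, 0.05)),))}
            props = None
        else:
            m19 = float(rng.uniform(6.0, 16.0))
            f19 = float(rng.uniform(1.8, 4.5))
            two_seg = rng.random() < 0.4
            if two_seg:
                bp = int(rng.integers(2007, 2014))
                trends = {"male": SexTrend(m19, (float(rng.uniform(0.05, 0.25)),
                                                 float(rng.uniform(-0.20, -0.02))), (bp,)),
                          "female": SexTrend(f19, (float(rng.uniform(-0.04, 0.06)),))}
            else:
                trends = {"male": SexTrend(m19, (float(rng.uniform(-0.12, 0.20)),)),
                          "female": SexTrend(f19, (float(rng.uniform(-0.05, 0.06)),))}
            props = {"male": (0.12, 0.08), "female": (0.06, 0.10)}
        countries.append(CountrySpec(code=code, trends=trends, props=props,
                                     population_total=pop))
    return SyntheticConfig(countries=countries, noise_sd=noise_sd, seed=seed)
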
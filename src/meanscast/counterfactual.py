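"""Counterfactual means-restriction scenarios.

A scenario is defined by a proportion threshold (e.g. 0.40 or 0.20): a
country implements a firearm or pesticide restriction in the intervention
year if the corresponding means accounts for at least that fraction of its
suicides for at least one sex.  Countries are screened first by a minimum
2019 both-sexes rate (a country with a very low rate would not realistically
legislate means restriction) and excluded when no means profile exists or
when their baseline forecast goes negative (the scaling algebra is undefined
for a negative baseline).

For a restricted country the forecast baseline rate of each sex-year is split
into the targeted-means component and the remainder using the frozen
reference-year proportion, and each component is multiplied by the
schedule's rate ratio for k = years since intervention:

    cf(t) = p * ASR(t) * rr_target(k) + (1 - p) * ASR(t) * rr_other(k)

rr_other captures means substitution -- it can exceed 1, in which case the
counterfactual can initially exceed the baseline when the targeted means is
rare.  Schedules shorter than the horizon carry their last entry forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEANS = ("firearm", "pesticide")


@dataclass
class ScenarioConfig:
    threshold: float = 0.40
    intervention_year: int = 2020
    final_year: int = 2030
    min_rate_2019: float = 3.0
    exclusion_reference_year: int = 2019

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        if self.intervention_year >= self.final_year:
            raise ValueError("intervention_year must precede final_year")


@dataclass
class EligibilityDecision:
    country: str
    decision: str  # restrict_firearm | restrict_pesticide | not_eligible
    reasons: list[str] = field(default_factory=list)


def both_sexes_rate(panel: pd.DataFrame, population: pd.DataFrame,
                    country: str, year: int) -> float:
    """Population-weighted both-sexes ASR for one country-year."""
    rows = panel[(panel["country"] == country) & (panel["year"] == year)]
    if len(rows) < 2:
        raise ValueError(f"missing {year} observation for {country}")
    pop = population[(population["country"] == country) & (population["year"] == year)]
    weights = pop.groupby("sex")["count"].sum()
    num = sum(r.asr * weights[r.sex] for r in rows.itertuples())
    return float(num / weights.sum())


def determine_eligibility(
    profiles: pd.DataFrame,
    panel: pd.DataFrame,
    forecasts: dict,
    population: pd.DataFrame,
    config: ScenarioConfig,
) -> dict[str, EligibilityDecision]:
    """Apply the scenario screening rules, in order, to every panel country.

    1. both-sexes rate in the exclusion reference year below ``min_rate_2019``
       -> not eligible;
    2. no means profile -> not eligible;
    3. a means qualifies if its proportion meets the threshold for at least
       one sex; if both means qualify the one with the larger maximum
       proportion wins;
    4. any raw-negative forecast point (either sex) -> not eligible.
    A granted restriction applies to both sexes.
    """
    decisions: dict[str, EligibilityDecision] = {}
    prof_by_country = {c: g for c, g in profiles.groupby("country")}
    for country in sorted(panel["country"].unique()):
        rate = both_sexes_rate(panel, population, country,
                               config.exclusion_reference_year)
        if rate < config.min_rate_2019:
            decisions[country] = EligibilityDecision(country, "not_eligible",
                                                     ["below_min_rate"])
            continue
        prof = prof_by_country.get(country)
        if prof is None:
            decisions[country] = EligibilityDecision(country, "not_eligible",
                                                     ["no_profile"])
            continue
        max_prop = {
            "firearm": float(prof["prop_firearm"].max()),
            "pesticide": float(prof["prop_pesticide"].max()),
        }
        qualifying = [m for m in MEANS if max_prop[m] >= config.threshold]
        if not qualifying:
            decisions[country] = EligibilityDecision(country, "not_eligible",
                                                     ["below_threshold"])
            continue
        chosen = max(qualifying, key=lambda m: max_prop[m])
        negative = any(
            forecasts[(country, sex)].has_negative_raw
            for sex in panel.loc[panel["country"] == country, "sex"].unique()
        )
        if negative:
            decisions[country] = EligibilityDecision(country, "not_eligible",
                                                     ["negative_forecast"])
            continue
        decisions[country] = EligibilityDecision(
            country, f"restrict_{chosen}", [f"eligible_{chosen}"])
    return decisions


def decompose_rate(asr: float, proportion: float) -> tuple[float, float]:
    """Split an ASR into (targeted-means rate, other-means rate)."""
    if not (0 <= proportion <= 1):
        raise ValueError("proportion must be in [0, 1]")
    means_rate = asr * proportion
    return means_rate, asr - means_rate


def schedule_lookup(schedules: pd.DataFrame, means: str, k: int) -> pd.Series:
    """Schedule row for (means, k); k beyond the table carries the last entry forward."""
    if k <= 0:
        raise ValueError("k (years since intervention) must be >= 1")
    grp = schedules[schedules["means"] == means]
    if grp.empty:
        raise KeyError(f"no rate-ratio schedule for means {means!r}")
    row = grp[grp["k"] == min(k, int(grp["k"].max()))]
    return row.iloc[0]


def apply_restriction(means_rate: float, other_rate: float,
                      rr_target: float, rr_other: float) -> float:
    """Counterfactual rate from the two components and their rate ratios."""
    return means_rate * rr_target + other_rate * rr_other


def run_scenario(
    forecasts: dict,
    profiles: pd.DataFrame,
    schedules: pd.DataFrame,
    eligibility: dict[str, EligibilityDecision],
    config: ScenarioConfig,
) -> pd.DataFrame:
    """Counterfactual rate table for every (country, sex, year) of the horizon.

    Restricted countries get the decomposition/rate-ratio algebra applied from
    the first post-intervention year (k = 1 at intervention_year + 1);
    everything else carries its baseline forecast unchanged so that
    aggregation sees the full region.
    """
    plook = {(r.country, r.sex): (r.prop_firearm, r.prop_pesticide)
             for r in profiles.itertuples()}
    rows = []
    for (country, sex), fc in sorted(forecasts.items()):
        dec = eligibility.get(country)
        restricted = dec is not None and dec.decision.startswith("restrict_")
        means = dec.decision.removeprefix("restrict_") if restricted else None
        if restricted and (country, sex) not in plook:
            raise KeyError(f"restricted country {country} lacks a {sex} profile")
        for year, baseline in zip(fc.years, fc.point):
            k = int(year) - config.intervention_year
            if restricted and k >= 1:
                pf, pp = plook[(country, sex)]
                prop = pf if means == "firearm" else pp
                means_rate, other_rate = decompose_rate(float(baseline), prop)
                row = schedule_lookup(schedules, means, k)
                cf = apply_restriction(means_rate, other_rate,
                                       float(row["rr_target"]), float(row["rr_other"]))
            else:
                means_rate, other_rate, cf = np.nan, np.nan, float(baseline)
            rows.append({
                "country": country, "sex": sex, "year": int(year),
                "baseline": float(baseline),
                "means_rate": means_rate, "other_rate": other_rate,
                "counterfactual": cf,
                "restricted": bool(restricted and k >= 1),
                "means": means if restricted else "",
            })
    return pd.DataFrame(rows)


def eligibility_table(decisions: dict[str, EligibilityDecision]) -> pd.DataFrame:
    return pd.DataFrame([
        {"country": d.country, "decision": d.decision, "reasons": ";".join(d.reasons)}
        for d in decisions.values()
    ])
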
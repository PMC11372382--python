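"""Deaths accounting and population-weighted rate aggregation.

Absolute deaths are recovered from an age-standardized rate trajectory under
a mirroring assumption: the proportional change in the ASR relative to the
base year applies uniformly to every age-specific rate.  With base-year
age-specific rates m_a (per 100,000) and projected populations N_a(t),

    deaths(t) = sum_a m_a * (ASR(t) / ASR(base)) * N_a(t) / 100,000

which collapses to ``ASR(t) * K(t)`` with K(t) = sum_a m_a N_a(t) / (1e5 *
ASR(base)) -- the per-country-sex-year conversion factor used throughout,
including inside the Monte Carlo loop.

Sub-regional and regional rates are population-weighted means of the member
country rates with year- and sex-specific total populations as weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PER = 100_000.0


def death_factors(
    base_age_rates: pd.DataFrame,
    population: pd.DataFrame,
    base_asr: pd.DataFrame,
    years: np.ndarray,
) -> pd.DataFrame:
    """K(country, sex, year) such that deaths = ASR * K.

    ``base_age_rates`` has columns country, sex, age_group, rate (per 100,000
    at the base year); ``base_asr`` has columns country, sex, asr (the
    base-year ASR).  Raises if a base ASR is zero -- the proportional scaling
    is undefined there.
    """
    merged = base_age_rates.merge(
        population[population["year"].isin(years)],
        on=["country", "sex", "age_group"], how="inner",
    )
    agg = (merged.assign(d=lambda f: f["rate"] * f["count"] / PER)
           .groupby(["country", "sex", "year"], as_index=False)["d"].sum())
    agg = agg.merge(base_asr[["country", "sex", "asr"]], on=["country", "sex"])
    if (agg["asr"] <= 0).any():
        bad = agg.loc[agg["asr"] <= 0, ["country", "sex"]].drop_duplicates()
        raise ValueError(f"zero base-year ASR, scaling undefined for:\n{bad.to_string(index=False)}")
    agg["factor"] = agg["d"] / agg["asr"]
    return agg[["country", "sex", "year", "factor"]]


def deaths_from_asr(rates: pd.DataFrame, factors: pd.DataFrame,
                    rate_col: str = "counterfactual") -> pd.DataFrame:
    """Deaths table from a rate table (country, sex, year, <rate_col>)."""
    merged = rates.merge(factors, on=["country", "sex", "year"], how="left")
    if merged["factor"].isna().any():
        bad = merged.loc[merged["factor"].isna(), ["country", "sex", "year"]]
        raise ValueError(f"no death factor for:\n{bad.head().to_string(index=False)}")
    merged["deaths"] = merged[rate_col] * merged["factor"]
    return merged[["country", "sex", "year", "deaths"]]


def avoided_deaths(baseline: pd.DataFrame, counterfactual: pd.DataFrame) -> pd.DataFrame:
    """Per-year avoided deaths (counterfactual - baseline; negative = avoided)."""
    keys = ["country", "sex", "year"]
    m = baseline.merge(counterfactual, on=keys, suffixes=("_base", "_cf"),
                       how="outer", indicator=True)
    if (m["_merge"] != "both").any():
        raise ValueError("baseline and counterfactual deaths tables are misaligned")
    m["avoided"] = m["deaths_cf"] - m["deaths_base"]
    return m[keys + ["avoided"]]


def _check_mapped(countries, mapping):
    unmapped = sorted(set(countries) - set(mapping))
    if unmapped:
        raise KeyError(f"countries without a subregion mapping: {unmapped}")


def aggregate_rates(
    rates: pd.DataFrame,
    population: pd.DataFrame,
    mapping: dict[str, str],
    rate_cols: tuple[str, ...] = ("baseline", "counterfactual"),
    region_label: str = "Region",
) -> pd.DataFrame:
    """Population-weighted subregional and regional rates per sex-year.

    Weights are the sex-specific total populations of the member countries in
    each year.  Returns one row per (scope, sex, year) where scope runs over
    the subregions plus the whole region.
    """
    _check_mapped(rates["country"].unique(), mapping)
    weights = (population.groupby(["country", "sex", "year"], as_index=False)["count"]
               .sum().rename(columns={"count": "w"}))
    m = rates.merge(weights, on=["country", "sex", "year"], how="left")
    if m["w"].isna().any():
        bad = m.loc[m["w"].isna(), ["country", "sex", "year"]].drop_duplicates()
        raise ValueError(f"no population weight for:\n{bad.head().to_string(index=False)}")
    m["scope"] = m["country"].map(mapping)

    def _weighted(group):
        out = {}
        for col in rate_cols:
            out[col] = float(np.average(group[col], weights=group["w"]))
        return pd.Series(out)

    sub = (m.groupby(["scope", "sex", "year"]).apply(_weighted, include_groups=False)
           .reset_index())
    reg = (m.assign(scope=region_label)
           .groupby(["scope", "sex", "year"]).apply(_weighted, include_groups=False)
           .reset_index())
    return pd.concat([sub, reg], ignore_index=True)


def aggregate_deaths(deaths: pd.DataFrame, mapping: dict[str, str],
                     value_col: str = "deaths",
                     region_label: str = "Region") -> pd.DataFrame:
    """Sum a per-country deaths (or avoided-deaths) table to subregions and the region."""
    _check_mapped(deaths["country"].unique(), mapping)
    d = deaths.assign(scope=deaths["country"].map(mapping))
    sub = d.groupby(["scope", "sex", "year"], as_index=False)[value_col].sum()
    reg = (d.assign(scope=region_label)
           .groupby(["scope", "sex", "year"], as_index=False)[value_col].sum())
    return pd.concat([sub, reg], ignore_index=True)


def cumulative_avoided(avoided: pd.DataFrame, value_col: str = "avoided",
                       scope_col: str = "scope") -> pd.DataFrame:
    """Cumulative avoided deaths over all years, per scope and sex."""
    return (avoided.groupby([scope_col, "sex"], as_index=False)[value_col]
            .sum().rename(columns={value_col: "cumulative"}))
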
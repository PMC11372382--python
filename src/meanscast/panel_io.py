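"""Reading, validation and writing of the tabular inputs and result tables.

All files are UTF-8, comma-delimited CSV with dot decimals.  The four input
tables are

* rate panel       -- ``country,sex,year,asr[,ci_low,ci_high]`` long format,
                      age-standardized suicide rates per 100,000;
* means profiles   -- ``country,sex,prop_firearm,prop_pesticide,reference_year``,
                      proportions of suicides involving each means, as
                      fractions in [0, 1];
* population table -- ``country,sex,age_group,year,count`` projected persons
                      by 5-year age band;
* rate-ratio schedule -- ``means,k,rr_target,rr_target_lo,rr_target_hi,
                      rr_other,rr_other_lo,rr_other_hi`` indexed by years
                      since intervention.

A country with no means profile is an explicit absence (the country is still
forecast and aggregated, it just cannot receive a restriction) -- it is never
coerced to zero proportions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEXES = ("male", "female")

RATE_COLUMNS = ["country", "sex", "year", "asr"]
RATE_CI_COLUMNS = ["ci_low", "ci_high"]
PROFILE_COLUMNS = ["country", "sex", "prop_firearm", "prop_pesticide", "reference_year"]
POPULATION_COLUMNS = ["country", "sex", "age_group", "year", "count"]
SCHEDULE_COLUMNS = [
    "means", "k",
    "rr_target", "rr_target_lo", "rr_target_hi",
    "rr_other", "rr_other_lo", "rr_other_hi",
]


class PanelValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def _data_path(name: str):
    return importlib.resources.files("meanscast.data").joinpath(name)


# ---------------------------------------------------------------------------
# rate panel
# ---------------------------------------------------------------------------

def validate_rate_panel(df: pd.DataFrame, window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Validate a long-format rate panel and return it sorted.

    Checks: required columns, known sexes, non-negative rates, CI bounds
    bracketing the point when present, uniqueness of (country, sex, year),
    and per-series year contiguity over the declared observation ``window``.
    """
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"rate panel missing columns: {missing}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["asr"] = df["asr"].astype(float)

    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise PanelValidationError(f"unknown sex labels: {sorted(bad_sex)}")
    if (df["asr"] < 0).any():
        rows = df.loc[df["asr"] < 0, RATE_COLUMNS]
        raise PanelValidationError(f"negative asr values:\n{rows.to_string(index=False)}")

    has_ci = all(c in df.columns for c in RATE_CI_COLUMNS)
    if has_ci:
        both = df["ci_low"].notna() & df["ci_high"].notna()
        sub = df.loc[both]
        if ((sub["ci_low"] - sub["asr"] > 1e-12) | (sub["asr"] - sub["ci_high"] > 1e-12)).any():
            raise PanelValidationError("CI bounds do not bracket asr")

    dup = df.duplicated(subset=["country", "sex", "year"])
    if dup.any():
        keys = df.loc[dup, ["country", "sex", "year"]].drop_duplicates()
        raise PanelValidationError(f"duplicate (country, sex, year) keys:\n{keys.to_string(index=False)}")

    if window is not None:
        lo, hi = window
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
        expected = set(range(lo, hi + 1))
    else:
        expected = None
    for (country, sex), grp in df.groupby(["country", "sex"], sort=False):
        years = set(grp["year"])
        want = expected if expected is not None else set(range(min(years), max(years) + 1))
        gaps = sorted(want - years)
        if gaps:
            raise PanelValidationError(
                f"series {country}/{sex} has missing years {gaps}"
            )
    return df.sort_values(["country", "sex", "year"]).reset_index(drop=True)


def read_rate_panel(path: str | Path, window: tuple[int, int] = (2000, 2019)) -> pd.DataFrame:
    """Read and validate a rate panel CSV restricted to ``window``."""
    df = pd.read_csv(path)
    return validate_rate_panel(df, window=window)


def write_rate_panel(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# means profiles
# ---------------------------------------------------------------------------

def validate_means_profiles(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"means profile missing columns: {missing}")
    df = df.copy()
    for col in ("prop_firearm", "prop_pesticide"):
        df[col] = df[col].astype(float)
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise PanelValidationError(f"{col} outside [0, 1]")
    total = df["prop_firearm"] + df["prop_pesticide"]
    if (total > 1 + 1e-12).any():
        rows = df.loc[total > 1 + 1e-12, ["country", "sex"]]
        raise PanelValidationError(
            f"prop_firearm + prop_pesticide > 1 for:\n{rows.to_string(index=False)}"
        )
    if df.duplicated(subset=["country", "sex"]).any():
        raise PanelValidationError("duplicate (country, sex) profile rows")
    return df.reset_index(drop=True)


def read_means_profiles(path: str | Path) -> pd.DataFrame:
    """Read means profiles; countries absent from the file simply have no row."""
    return validate_means_profiles(pd.read_csv(path))


def profile_lookup(profiles: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    """Map (country, sex) -> (prop_firearm, prop_pesticide); absent keys mean no profile."""
    return {
        (r.country, r.sex): (r.prop_firearm, r.prop_pesticide)
        for r in profiles.itertuples()
    }


def countries_without_profile(profiles: pd.DataFrame, countries: Iterable[str]) -> list[str]:
    """Countries in the panel with no profile row for either sex."""
    have = set(profiles["country"])
    return sorted(set(countries) - have)


# ---------------------------------------------------------------------------
# population table
# ---------------------------------------------------------------------------

def validate_population(df: pd.DataFrame, age_bands: list[str] | None = None) -> pd.DataFrame:
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"population table missing columns: {missing}")
    df = df.copy()
    df["count"] = df["count"].astype(float)
    df["year"] = df["year"].astype(int)
    if (df["count"] < 0).any():
        raise PanelValidationError("negative population counts")
    bands = age_bands if age_bands is not None else standard_age_bands()
    unknown = set(df["age_group"]) - set(bands)
    if unknown:
        raise PanelValidationError(f"unknown age band labels: {sorted(unknown)}")
    # identical band set across countries and years
    expected = set(df["age_group"].unique())
    counts = df.groupby(["country", "sex", "year"])["age_group"].apply(set)
    bad = counts[counts != expected]
    if len(bad):
        raise PanelValidationError(
            f"age band set differs for {list(bad.index[:5])} (and possibly more)"
        )
    return df.reset_index(drop=True)


def read_population(path: str | Path, age_bands: list[str] | None = None) -> pd.DataFrame:
    return validate_population(pd.read_csv(path), age_bands=age_bands)


# ---------------------------------------------------------------------------
# rate-ratio schedules
# ---------------------------------------------------------------------------

def validate_schedule(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"rate-ratio schedule missing columns: {missing}")
    df = df.copy()
    df["k"] = df["k"].astype(int)
    for col in SCHEDULE_COLUMNS[2:]:
        df[col] = df[col].astype(float)
        if (df[col] <= 0).any():
            raise PanelValidationError(f"non-positive rate ratio in column {col}")
    for means, grp in df.groupby("means"):
        ks = sorted(grp["k"])
        if ks != list(range(1, len(ks) + 1)):
            raise PanelValidationError(
                f"schedule for {means!r} must cover k = 1..n contiguously, got {ks}"
            )
    return df.sort_values(["means", "k"]).reset_index(drop=True)


def read_schedules(path: str | Path) -> pd.DataFrame:
    """Read a rate-ratio schedule CSV (lines starting with ``#`` are comments)."""
    return validate_schedule(pd.read_csv(path, comment="#"))


def template_schedules() -> pd.DataFrame:
    """The bundled synthetic schedule template (placeholder values, not literature estimates)."""
    with importlib.resources.as_file(_data_path("rate_ratio_template.csv")) as p:
        return read_schedules(p)


# ---------------------------------------------------------------------------
# bundled reference tables
# ---------------------------------------------------------------------------

def load_subregions() -> pd.DataFrame:
    """Bundled PAHO subregion membership for the 33 countries of the Americas."""
    with importlib.resources.as_file(_data_path("subregions.csv")) as p:
        return pd.read_csv(p)


def subregion_map(table: pd.DataFrame | None = None) -> dict[str, str]:
    table = load_subregions() if table is None else table
    return dict(zip(table["country_code"], table["subregion"]))


def country_name_map() -> dict[str, str]:
    table = load_subregions()
    return dict(zip(table["country_code"], table["country_name"]))


def load_standard_population() -> pd.DataFrame:
    """WHO world standard population weights by 5-year band, normalized to sum 1."""
    with importlib.resources.as_file(_data_path("who_standard_population.csv")) as p:
        df = pd.read_csv(p)
    df["weight"] = df["weight"] / df["weight"].sum()
    return df


def standard_age_bands() -> list[str]:
    return list(load_standard_population()["age_group"])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], directory: str | Path) -> list[Path]:
    """Write each named result table to ``directory/<name>.csv``; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, table in tables.items():
        path = directory / f"{name}.csv"
        table.to_csv(path, index=False)
        out.append(path)
    return out
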
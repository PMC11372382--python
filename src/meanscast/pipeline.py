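"""End-to-end orchestration: simulate -> forecast -> scenario -> report.

Each stage is a plain function over the library modules; the CLI and the
analysis drivers are thin wrappers around these.  A run manifest (input
digests, config snapshot, seeds, per-series model choices, eligibility
decisions) is emitted alongside the outputs so any table can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import counterfactual, deaths, forecasting, joinpoint, monte_carlo, panel_io

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(directory: Path, **payload) -> Path:
    manifest = {
        "package_version": __version__,
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        **payload,
    }
    path = Path(directory) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def run_forecast_stage(
    panel: pd.DataFrame,
    horizon: tuple[int, int] = (2020, 2030),
    max_joinpoints: int = 3,
):
    """Joinpoint description plus vetted forecasts for every series.

    Returns (forecast_table, forecasts_by_series, joinpoint_table, decision_log).
    """
    jp = joinpoint.joinpoint_table(panel, max_joinpoints=max_joinpoints)
    fc_table, fc_objs, log = forecasting.forecast_panel(panel, jp, horizon=horizon)
    for line in log:
        logger.info("model choice: %s", line)
    return fc_table, fc_objs, jp, log


def run_scenario_stage(
    forecasts: dict,
    panel: pd.DataFrame,
    profiles: pd.DataFrame,
    schedules: pd.DataFrame,
    population: pd.DataFrame,
    base_age_rates: pd.DataFrame,
    base_asr: pd.DataFrame,
    config: counterfactual.ScenarioConfig,
    mapping: dict[str, str] | None = None,
    uncertainty: monte_carlo.UncertaintySpec | None = None,
):
    """Full scenario evaluation at country, subregion and region level.

    Returns a dict of result tables: eligibility, counterfactual rates,
    aggregated rates, country deaths, yearly and cumulative avoided deaths
    (with uncertainty intervals when an UncertaintySpec is given).
    """
    mapping = panel_io.subregion_map() if mapping is None else mapping
    eligibility = counterfactual.determine_eligibility(
        profiles, panel, forecasts, population, config)
    cf = counterfactual.run_scenario(forecasts, profiles, schedules, eligibility, config)

    horizon_years = np.arange(config.intervention_year, config.final_year + 1)
    factors = deaths.death_factors(base_age_rates, population, base_asr, horizon_years)
    base_d = deaths.deaths_from_asr(cf, factors, rate_col="baseline")
    cf_d = deaths.deaths_from_asr(cf, factors, rate_col="counterfactual")
    avoided = deaths.avoided_deaths(base_d, cf_d)
    post = avoided["year"] > config.intervention_year

    agg_rates = deaths.aggregate_rates(cf, population, mapping)
    avoided_scoped = deaths.aggregate_deaths(avoided[post], mapping, value_col="avoided")
    cumulative = deaths.cumulative_avoided(avoided_scoped)

    if uncertainty is not None:
        yearly_ui, cum_ui = monte_carlo.run_monte_carlo(
            forecasts, profiles, schedules, eligibility, config,
            factors, mapping, uncertainty)
        avoided_scoped = yearly_ui
        cumulative = cum_ui

    return {
        "eligibility": counterfactual.eligibility_table(eligibility),
        "rates_country": cf,
        "rates_aggregated": agg_rates,
        "deaths_baseline": base_d,
        "deaths_counterfactual": cf_d,
        "avoided_country": avoided[post].reset_index(drop=True),
        "avoided": avoided_scoped,
        "avoided_cumulative": cumulative,
    }


def scenario_summary(results: dict) -> dict:
    """Headline numbers of a scenario run: restricted counts and cumulative avoided deaths."""
    elig = results["eligibility"]
    restricted = elig[elig["decision"].str.startswith("restrict_")]
    cum = results["avoided_cumulative"]
    region = cum[cum["scope"] == "Region"].set_index("sex")
    col = "avoided" if "avoided" in region.columns else "cumulative"
    return {
        "n_restricted": int(len(restricted)),
        "n_firearm": int((restricted["decision"] == "restrict_firearm").sum()),
        "n_pesticide": int((restricted["decision"] == "restrict_pesticide").sum()),
        "restricted_countries": sorted(restricted["country"]),
        "cumulative_avoided_male": float(region.loc["male", col]),
        "cumulative_avoided_female": float(region.loc["female", col]),
    }
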
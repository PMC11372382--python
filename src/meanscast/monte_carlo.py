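"""Monte Carlo propagation of forecast and rate-ratio uncertainty.

Avoided-deaths uncertainty intervals are 2.5th/97.5th percentiles of 1000
re-evaluations of the counterfactual algebra with sampled inputs:

* forecast rates are drawn from a normal distribution centred on the point
  forecast with sd implied by the 95% prediction interval, truncated at zero
  (a rate cannot be negative -- the truncation is the per-draw analogue of
  the zero imputation applied to negative point forecasts);
* rate ratios are drawn from a lognormal with median equal to the point RR
  and log-sd implied by the 95% CI.  One RR draw per (means, k, component)
  is shared by every country under that restriction within a draw: the RR is
  a single literature estimate whose error is systematic, not per-country.

Within each draw the baseline arm and the counterfactual arm of a restricted
country use independent rate draws, so the avoided-deaths distribution
reflects uncertainty in both trajectories; under the null (all RRs = 1) the
interval therefore straddles zero while the point estimate -- which is always
the deterministic run, never the draw mean -- is exactly zero.  Unrestricted
countries contribute no avoided deaths in any draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counterfactual import MEANS, ScenarioConfig, schedule_lookup

Z95 = 1.959963984540054  # normal quantile behind a 95% interval


@dataclass
class UncertaintySpec:
    n_draws: int = 1000
    seed: int = 20240716
    include_rate_uncertainty: bool = True
    include_rr_uncertainty: bool = True

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")


def sample_rr(rr, ci_low, ci_high, rng, size=None):
    """Lognormal draw(s) with median ``rr`` and sigma from the 95% CI width."""
    rr, lo, hi = float(rr), float(ci_low), float(ci_high)
    if lo <= 0 or hi <= 0 or rr <= 0:
        raise ValueError("rate ratio and CI bounds must be positive")
    if not (lo <= rr <= hi):
        raise ValueError("CI bounds must bracket the rate ratio")
    sigma = (np.log(hi) - np.log(lo)) / (2 * Z95)
    if sigma == 0:
        return rr if size is None else np.full(size, rr)
    return np.exp(np.log(rr) + sigma * rng.standard_normal(size))


def sample_rate(point, lo, hi, rng, size=None):
    """Truncated-normal draw(s): mean ``point``, sd from the 95% interval, support [0, inf)."""
    point = np.asarray(point, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if (lo > hi).any():
        raise ValueError("interval lower bound exceeds upper bound")
    sd = (hi - lo) / (2 * Z95)
    shape = point.shape if size is None else size
    out = np.broadcast_to(point, shape).copy()
    sd_b = np.broadcast_to(sd, shape)
    mask = sd_b > 0
    if mask.any():
        a = (0.0 - np.broadcast_to(point, shape)[mask]) / sd_b[mask]
        out[mask] = stats.truncnorm.rvs(
            a, np.inf, loc=np.broadcast_to(point, shape)[mask],
            scale=sd_b[mask], random_state=rng,
        )
    return out


def _rr_arrays(schedules: pd.DataFrame, horizon_k: int):
    """Point/lo/hi arrays of shape (n_means, horizon_k) with carry-forward."""
    point_t = np.ones((len(MEANS), horizon_k))
    lo_t = np.ones_like(point_t)
    hi_t = np.ones_like(point_t)
    point_o = np.ones_like(point_t)
    lo_o = np.ones_like(point_t)
    hi_o = np.ones_like(point_t)
    present = set(schedules["means"])
    for mi, means in enumerate(MEANS):
        if means not in present:
            continue
        for k in range(1, horizon_k + 1):
            row = schedule_lookup(schedules, means, k)
            point_t[mi, k - 1] = row["rr_target"]
            lo_t[mi, k - 1] = row["rr_target_lo"]
            hi_t[mi, k - 1] = row["rr_target_hi"]
            point_o[mi, k - 1] = row["rr_other"]
            lo_o[mi, k - 1] = row["rr_other_lo"]
            hi_o[mi, k - 1] = row["rr_other_hi"]
    return (point_t, lo_t, hi_t), (point_o, lo_o, hi_o)


def _sample_rr_block(point, lo, hi, rng, n_draws):
    """Shared RR draws, shape (n_draws, n_means, K)."""
    sigma = (np.log(hi) - np.log(lo)) / (2 * Z95)
    z = rng.standard_normal((n_draws,) + point.shape)
    return np.exp(np.log(point)[None] + sigma[None] * z)


def run_monte_carlo(
    forecasts: dict,
    profiles: pd.DataFrame,
    schedules: pd.DataFrame,
    eligibility: dict,
    config: ScenarioConfig,
    factors: pd.DataFrame,
    mapping: dict[str, str],
    spec: UncertaintySpec,
    region_label: str = "Region",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uncertainty intervals for yearly and cumulative avoided deaths per scope.

    Returns ``(yearly, cumulative)`` frames with columns scope, sex, year
    (yearly only), avoided (deterministic point), ui_low, ui_high.
    """
    from . import deaths as deaths_mod
    from .counterfactual import run_scenario

    rng = np.random.default_rng(spec.seed)
    horizon_k = config.final_year - config.intervention_year

    # deterministic point estimate
    cf_table = run_scenario(forecasts, profiles, schedules, eligibility, config)
    base_d = deaths_mod.deaths_from_asr(cf_table, factors, rate_col="baseline")
    cf_d = deaths_mod.deaths_from_asr(cf_table, factors, rate_col="counterfactual")
    avoided = deaths_mod.avoided_deaths(base_d, cf_d)
    post = avoided["year"] > config.intervention_year
    point_yearly = deaths_mod.aggregate_deaths(avoided[post], mapping,
                                               value_col="avoided",
                                               region_label=region_label)

    # restricted (country, sex) pairs drive the draws
    plook = {(r.country, r.sex): (r.prop_firearm, r.prop_pesticide)
             for r in profiles.itertuples()}
    flook = {(r.country, r.sex, r.year): r.factor for r in factors.itertuples()}
    pairs = []
    for (country, sex), fc in sorted(forecasts.items()):
        dec = eligibility.get(country)
        if dec is None or not dec.decision.startswith("restrict_"):
            continue
        means = dec.decision.removeprefix("restrict_")
        mi = MEANS.index(means)
        pf, pp = plook[(country, sex)]
        prop = pf if means == "firearm" else pp
        pairs.append((country, sex, mi, prop, fc))

    years_post = np.arange(config.intervention_year + 1, config.final_year + 1)
    scopes = sorted(set(mapping.values())) + [region_label]
    n = spec.n_draws

    if pairs:
        P, Y = len(pairs), len(years_post)
        point = np.empty((P, Y))
        lo = np.empty((P, Y))
        hi = np.empty((P, Y))
        fac = np.empty((P, Y))
        prop_arr = np.empty(P)
        mi_arr = np.empty(P, dtype=int)
        for i, (country, sex, mi, prop, fc) in enumerate(pairs):
            sel = np.isin(fc.years, years_post)
            point[i] = fc.point[sel]
            lo[i] = fc.lo[sel]
            hi[i] = fc.hi[sel]
            prop_arr[i] = prop
            mi_arr[i] = mi
            fac[i] = [flook[(country, sex, int(y))] for y in years_post]

        if spec.include_rr_uncertainty:
            (pt_t, lo_t, hi_t), (pt_o, lo_o, hi_o) = _rr_arrays(schedules, horizon_k)
            rr_t = _sample_rr_block(pt_t, lo_t, hi_t, rng, n)
            rr_o = _sample_rr_block(pt_o, lo_o, hi_o, rng, n)
        else:
            (pt_t, _, _), (pt_o, _, _) = _rr_arrays(schedules, horizon_k)
            rr_t = np.broadcast_to(pt_t, (n,) + pt_t.shape)
            rr_o = np.broadcast_to(pt_o, (n,) + pt_o.shape)

        if spec.include_rate_uncertainty:
            r_base = sample_rate(point, lo, hi, rng, size=(n, P, Y))
            r_cf = sample_rate(point, lo, hi, rng, size=(n, P, Y))
        else:
            r_base = np.broadcast_to(point, (n, P, Y))
            r_cf = np.broadcast_to(point, (n, P, Y))

        k_idx = years_post - config.intervention_year - 1  # k-1 per year column
        rrt = rr_t[:, mi_arr][:, :, k_idx]  # (n, P, Y)
        rro = rr_o[:, mi_arr][:, :, k_idx]
        cf_rate = prop_arr[None, :, None] * r_cf * rrt + \
            (1 - prop_arr[None, :, None]) * r_cf * rro
        avoided_draws = (cf_rate - r_base) * fac[None]  # (n, P, Y)
    else:
        avoided_draws = np.zeros((n, 0, len(years_post)))

    # aggregate draws to scopes (unrestricted countries contribute exactly 0)
    yearly_rows, cum_rows = [], []
    pair_scope = np.array([mapping[c] for c, *_ in pairs]) if pairs else np.array([])
    pair_sex = np.array([s for _, s, *_ in pairs]) if pairs else np.array([])
    point_cum = deaths_mod.cumulative_avoided(point_yearly)
    point_yearly_ix = point_yearly.set_index(["scope", "sex", "year"])["avoided"]
    point_cum_ix = point_cum.set_index(["scope", "sex"])["cumulative"]
    for scope in scopes:
        for sex in sorted(set(s for _, s in forecasts.keys())):
            if len(pairs):
                in_scope = (pair_sex == sex) if scope == region_label else \
                    (pair_scope == scope) & (pair_sex == sex)
                draws = avoided_draws[:, in_scope, :].sum(axis=1)  # (n, Y)
            else:
                draws = np.zeros((n, len(years_post)))
            ui = np.percentile(draws, [2.5, 97.5], axis=0)
            for j, year in enumerate(years_post):
                yearly_rows.append({
                    "scope": scope, "sex": sex, "year": int(year),
                    "avoided": float(point_yearly_ix.get((scope, sex, int(year)), 0.0)),
                    "ui_low": float(ui[0, j]), "ui_high": float(ui[1, j]),
                })
            cum_draws = draws.sum(axis=1)
            cum_ui = np.percentile(cum_draws, [2.5, 97.5])
            cum_rows.append({
                "scope": scope, "sex": sex,
                "avoided": float(point_cum_ix.get((scope, sex), 0.0)),
                "ui_low": float(cum_ui[0]), "ui_high": float(cum_ui[1]),
            })
    return pd.DataFrame(yearly_rows), pd.DataFrame(cum_rows)
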
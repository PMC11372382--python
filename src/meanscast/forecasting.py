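"""Forecasting of age-standardized rate series to a fixed horizon.

Three forecast models are available for each country-sex series observed over
the fitting window (default 2000-2019):

``linear``
    OLS of the rate on calendar year, extrapolated with classical 95%
    prediction intervals.
``arima``
    ARIMA(p, d, q) with (p, d, q) selected by AICc over p, q in {0, 1, 2} and
    d in {0, 1}; a drift term is included (constant mean for d = 0, linear
    drift for d = 1) so trended series extrapolate their trend.
``lowess_arima``
    A LOWESS smoother (span 0.2) is applied to the observed series first and
    the auto-selected ARIMA is fit to the smoothed values; prediction
    intervals come from the ARIMA stage only (smoothing uncertainty is not
    propagated).

Model choice per series: the linear and ARIMA candidates are vetted against
the final joinpoint segment (sign and magnitude of the early forecast slope
must agree with the recent observed trend); the first candidate that passes
wins, and if neither does the LOWESS+ARIMA hybrid is used unconditionally.

Negative point forecasts are floored at zero and flagged -- a mortality rate
cannot be negative, and downstream deaths accounting relies on the flag to
know where flooring occurred.

Degenerate series whose linear fit is exact (zero residual) are extrapolated
in closed form by every method: maximum-likelihood ARIMA is ill-conditioned
as the innovation variance tends to zero, while the limit forecast is the
line itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOWESS_SPAN = 0.2
ARIMA_GRID = [(p, d, q) for p, d, q in product((0, 1, 2), (0, 1), (0, 1, 2))]
_EXACT_TOL = 1e-8  # max |residual| below which a linear fit counts as exact


@dataclass
class ForecastModelSpec:
    method: str = "linear"  # linear | arima | lowess_arima
    arima_order: tuple[int, int, int] | str = "auto"
    lowess_span: float = LOWESS_SPAN

    def __post_init__(self):
        if self.method not in ("linear", "arima", "lowess_arima"):
            raise ValueError(f"unknown forecast method {self.method!r}")
        if not (0 < self.lowess_span <= 1):
            raise ValueError("lowess_span must be in (0, 1]")


@dataclass
class ForecastSeries:
    country: str
    sex: str
    years: np.ndarray          # horizon years
    point: np.ndarray          # floored point forecasts, per 100,000
    lo: np.ndarray             # floored lower 95% bounds
    hi: np.ndarray             # upper 95% bounds
    raw_point: np.ndarray      # pre-flooring point forecasts
    floored: np.ndarray        # bool per year
    spec: ForecastModelSpec
    aicc: float = float("nan")

    @property
    def has_negative_raw(self) -> bool:
        return bool((self.raw_point < 0).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "country": self.country,
            "sex": self.sex,
            "year": self.years,
            "point": self.point,
            "lo": self.lo,
            "hi": self.hi,
            "raw_point": self.raw_point,
            "floored": self.floored,
            "method": self.spec.method,
        })


def _aicc_from_aic(aic: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _linear_forecast(years, y, horizon):
    """OLS on year with classical 95% prediction intervals; returns (point, lo, hi, aicc)."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(years, dtype=float))
    model = sm.OLS(np.asarray(y, dtype=float), X).fit()
    Xf = sm.add_constant(np.asarray(horizon, dtype=float), has_constant="add")
    pred = model.get_prediction(Xf)
    frame = pred.summary_frame(alpha=0.05)
    point = frame["mean"].to_numpy()
    lo = frame["obs_ci_lower"].to_numpy()
    hi = frame["obs_ci_upper"].to_numpy()
    aicc = _aicc_from_aic(model.aic, k=3, n=len(y))  # intercept, slope, sigma2
    return point, lo, hi, aicc


def _is_exactly_linear(years, y) -> bool:
    years = np.asarray(years, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(years), years])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return bool(np.max(np.abs(y - X @ coef)) < _EXACT_TOL * max(1.0, np.max(np.abs(y))))


def _closed_form_line(years, y, horizon):
    years = np.asarray(years, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(years), years])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    point = coef[0] + coef[1] * np.asarray(horizon, dtype=float)
    return point, point.copy(), point.copy(), -np.inf


def _fit_arima(y, order):
    from statsmodels.tsa.arima.model import ARIMA

    trend = "c" if order[1] == 0 else "t"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(np.asarray(y, dtype=float), order=order, trend=trend)
        return model.fit()


def _auto_arima(y):
    """Best ARIMA over the small grid by AICc; returns (result, order, aicc)."""
    best = None
    for order in ARIMA_GRID:
        try:
            res = _fit_arima(y, order)
        except Exception:
            continue
        aicc = res.aicc
        if not np.isfinite(aicc):
            continue
        if best is None or aicc < best[2]:
            best = (res, order, aicc)
    return best


def _arima_forecast(y, horizon_len, order):
    if order == "auto":
        best = _auto_arima(y)
        if best is None:
            raise RuntimeError("no ARIMA candidate converged")
        res, order, aicc = best
    else:
        res = _fit_arima(y, order)
        aicc = res.aicc
    fc = res.get_forecast(horizon_len)
    ci = fc.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    return np.asarray(fc.predicted_mean), ci[:, 0], ci[:, 1], float(aicc)


def _lowess_smooth(years, y, span):
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sm = lowess(np.asarray(y, float), np.asarray(years, float),
                frac=span, return_sorted=True)
    return sm[:, 1]


def fit_and_forecast(
    country: str,
    sex: str,
    years: np.ndarray,
    rates: np.ndarray,
    spec: ForecastModelSpec,
    horizon: tuple[int, int] = (2020, 2030),
) -> ForecastSeries:
    """Fit ``spec`` to one series and forecast the horizon with flooring.

    An ARIMA fit that fails to converge (or a hybrid whose ARIMA stage fails)
    falls back to the linear model with a logged warning.
    """
    years = np.asarray(years, dtype=int)
    y = np.asarray(rates, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 observations to forecast")
    horizon_years = np.arange(horizon[0], horizon[1] + 1)
    spec_used = spec

    if _is_exactly_linear(years, y):
        point, lo, hi, aicc = _closed_form_line(years, y, horizon_years)
    elif spec.method == "linear":
        point, lo, hi, aicc = _linear_forecast(years, y, horizon_years)
    else:
        series = y
        if spec.method == "lowess_arima":
            series = _lowess_smooth(years, y, spec.lowess_span)
            if _is_exactly_linear(years, series):
                point, lo, hi, aicc = _closed_form_line(years, series, horizon_years)
                series = None
        if series is not None:
            try:
                point, lo, hi, aicc = _arima_forecast(series, len(horizon_years), spec.arima_order)
            except Exception as exc:  # non-invertible / non-stationary / no convergence
                logger.warning("ARIMA failed for %s/%s (%s); falling back to linear",
                               country, sex, exc)
                point, lo, hi, aicc = _linear_forecast(years, y, horizon_years)
                spec_used = ForecastModelSpec(method="linear")

    raw = point.copy()
    floored = raw < 0
    point = np.maximum(point, 0.0)
    lo = np.maximum(lo, 0.0)
    hi = np.maximum(hi, point)  # keep bounds bracketing after flooring
    return ForecastSeries(country=country, sex=sex, years=horizon_years,
                          point=point, lo=lo, hi=hi, raw_point=raw,
                          floored=floored, spec=spec_used, aicc=aicc)


def vet_against_joinpoint(
    forecast: ForecastSeries,
    last_seg: tuple[int, float],
    slope_tolerance: float = 0.05,
) -> bool:
    """Does the forecast's early trend align with the last joinpoint segment?

    The slope over the forecast's first five years (raw, pre-flooring) must
    not oppose the final segment slope in sign, and must agree in magnitude
    within ``max(0.5 * |segment slope|, slope_tolerance)`` per 100,000 per
    year.  This operationalizes the visual "does the extrapolation continue
    the recent trend" check as a reproducible rule.
    """
    _, seg_slope = last_seg
    t = forecast.years[:5].astype(float)
    f = forecast.raw_point[:5]
    fc_slope = np.polyfit(t, f, 1)[0]
    if fc_slope * seg_slope < 0:
        return False
    tol = max(0.5 * abs(seg_slope), slope_tolerance)
    return bool(abs(fc_slope - seg_slope) <= tol)


@dataclass
class ForecastDecision:
    chosen: ForecastSeries
    trail: list[str] = field(default_factory=list)


def select_forecast(
    country: str,
    sex: str,
    years: np.ndarray,
    rates: np.ndarray,
    joinpoint_last_seg: tuple[int, float],
    horizon: tuple[int, int] = (2020, 2030),
    slope_tolerance: float = 0.05,
) -> ForecastDecision:
    """Pick the forecast model for one series.

    Candidates are tried in order (linear, then auto-ARIMA) and the first one
    whose extrapolation passes the joinpoint vetting wins.  If neither passes,
    the LOWESS+ARIMA hybrid is returned unconditionally -- mirroring the role
    of the smoother as the fallback for series whose global fits do not track
    the recent trend.
    """
    trail: list[str] = []
    candidates = [ForecastModelSpec(method="linear"), ForecastModelSpec(method="arima")]
    for spec in candidates:
        try:
            fc = fit_and_forecast(country, sex, years, rates, spec, horizon=horizon)
        except Exception as exc:
            trail.append(f"{spec.method}: fit failed ({exc})")
            continue
        ok = vet_against_joinpoint(fc, joinpoint_last_seg, slope_tolerance)
        trail.append(f"{spec.method}: aicc={fc.aicc:.2f} vetting={'pass' if ok else 'fail'}")
        if ok:
            return ForecastDecision(chosen=fc, trail=trail)
    fc = fit_and_forecast(country, sex, years, rates,
                          ForecastModelSpec(method="lowess_arima"), horizon=horizon)
    trail.append("lowess_arima: selected unconditionally after vetting failures")
    return ForecastDecision(chosen=fc, trail=trail)


def forecast_panel(
    panel: pd.DataFrame,
    joinpoints: pd.DataFrame,
    horizon: tuple[int, int] = (2020, 2030),
) -> tuple[pd.DataFrame, dict[tuple[str, str], ForecastSeries], list[str]]:
    """Select and compute forecasts for every (country, sex) series in a panel.

    Returns the long-format forecast table, the ForecastSeries objects keyed
    by (country, sex), and the decision log.
    """
    jp = joinpoints.set_index(["country", "sex"])
    frames, objs, log = [], {}, []
    for (country, sex), grp in panel.groupby(["country", "sex"], sort=True):
        grp = grp.sort_values("year")
        seg = jp.loc[(country, sex)]
        decision = select_forecast(
            country, sex, grp["year"].to_numpy(), grp["asr"].to_numpy(),
            (int(seg["last_segment_start"]), float(seg["last_segment_slope"])),
            horizon=horizon,
        )
        frames.append(decision.chosen.to_frame())
        objs[(country, sex)] = decision.chosen
        log.append(f"{country}/{sex}: " + " | ".join(decision.trail))
    return pd.concat(frames, ignore_index=True), objs, log
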
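"""Joinpoint (continuous piecewise-linear) trend regression for rate series.

The trend of each country-sex rate series is described by a continuous
piecewise-linear mean function with breakpoints ("joinpoints") restricted to
observed integer years.  For a candidate set of breakpoints b_1 < ... < b_m
the mean is

    E[y | t] = a + b t + sum_j d_j (t - b_j)_+

fit by ordinary least squares; the number of joinpoints is chosen by BIC over
an exhaustive grid of admissible placements (at least ``min_seg`` observations
per segment, breakpoints strictly inside the window).  The selected model's
final segment supplies the "recent trend" slope used to vet forecasts.

Fitting on the natural rate scale, not the log scale: the downstream forecast
models extrapolate rates directly, so the trend description must live on the
same scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np


@dataclass(frozen=True)
class JoinpointFit:
    """A selected piecewise-linear trend model.

    ``segment_slopes[i]`` and ``segment_intercepts[i]`` describe segment ``i``
    as ``y = intercept + slope * year`` on that segment's year range.
    """

    breakpoint_years: tuple[int, ...]
    segment_slopes: tuple[float, ...]
    segment_intercepts: tuple[float, ...]
    sse: float
    selection_score: float  # BIC of the selected model

    @property
    def n_segments(self) -> int:
        return len(self.breakpoint_years) + 1

    def predict(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        out = self.segment_intercepts[0] + self.segment_slopes[0] * years
        for b, s_prev, s_next, i_next in zip(
            self.breakpoint_years,
            self.segment_slopes[:-1],
            self.segment_slopes[1:],
            self.segment_intercepts[1:],
        ):
            mask = years >= b
            out = np.where(mask, i_next + s_next * years, out)
        return out


def _design(years: np.ndarray, breaks: tuple[int, ...]) -> np.ndarray:
    cols = [np.ones_like(years, dtype=float), years.astype(float)]
    for b in breaks:
        cols.append(np.clip(years - b, 0, None).astype(float))
    return np.column_stack(cols)


def _fit_breaks(years: np.ndarray, y: np.ndarray, breaks: tuple[int, ...]):
    X = _design(years, breaks)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _bic(sse: float, n: int, n_breaks: int) -> float:
    # each joinpoint costs a location and a slope change on top of intercept+slope
    k = 2 + 2 * n_breaks
    return n * np.log(max(sse, 1e-12) / n) + k * np.log(n)


def candidate_breakpoints(years: np.ndarray, n_breaks: int, min_seg: int = 3):
    """All admissible placements of ``n_breaks`` joinpoints on observed years.

    A joinpoint at year b ends one segment and starts the next; the boundary
    observation is shared, so a segment between joinpoints b_i and b_{i+1}
    holds the observations in [b_i, b_{i+1}].
    """
    years = np.sort(np.asarray(years))
    if n_breaks == 0:
        yield ()
        return
    # interior candidates: first/last year cannot be a joinpoint
    interior = years[1:-1]
    idx = {y: i for i, y in enumerate(years)}
    for combo in combinations(interior, n_breaks):
        bounds = [years[0], *combo, years[-1]]
        ok = all(
            idx[hi] - idx[lo] + 1 >= min_seg
            for lo, hi in zip(bounds[:-1], bounds[1:])
        )
        if ok:
            yield tuple(int(b) for b in combo)


def _segments_from_coef(years, coef, breaks):
    slopes, intercepts = [], []
    a, b = coef[0], coef[1]
    slopes.append(b)
    intercepts.append(a)
    for j, bk in enumerate(breaks):
        b = b + coef[2 + j]
        a = a - coef[2 + j] * bk
        slopes.append(b)
        intercepts.append(a)
    return tuple(float(s) for s in slopes), tuple(float(i) for i in intercepts)


def fit_joinpoint(
    years: np.ndarray,
    rates: np.ndarray,
    max_joinpoints: int = 3,
    min_seg: int = 3,
) -> JoinpointFit:
    """Fit and select a joinpoint model for one rate series.

    The number of joinpoints is chosen by BIC over 0..``max_joinpoints``; for
    each count the breakpoint placement is the exhaustive least-squares
    optimum.  Ties in BIC go to fewer joinpoints.
    """
    years = np.asarray(years, dtype=int)
    y = np.asarray(rates, dtype=float)
    n = len(years)
    if n != len(y):
        raise ValueError("years and rates must have equal length")
    if n < 2 * (max_joinpoints + 1) + 2:
        raise ValueError(
            f"series of length {n} too short for max_joinpoints={max_joinpoints}; "
            f"need at least {2 * (max_joinpoints + 1) + 2} observations -- lower max_joinpoints"
        )
    order = np.argsort(years)
    years, y = years[order], y[order]

    best = None
    for m in range(max_joinpoints + 1):
        best_m = None
        for breaks in candidate_breakpoints(years, m, min_seg=min_seg):
            coef, sse = _fit_breaks(years, y, breaks)
            if best_m is None or sse < best_m[1]:
                best_m = (coef, sse, breaks)
        if best_m is None:
            continue
        coef, sse, breaks = best_m
        score = _bic(sse, n, m)
        if best is None or score < best[0] - 1e-12:
            best = (score, coef, sse, breaks)

    score, coef, sse, breaks = best
    slopes, intercepts = _segments_from_coef(years, coef, breaks)
    return JoinpointFit(
        breakpoint_years=breaks,
        segment_slopes=slopes,
        segment_intercepts=intercepts,
        sse=sse,
        selection_score=float(score),
    )


def last_segment(fit: JoinpointFit, years: np.ndarray) -> tuple[int, float]:
    """(start_year, slope) of the final trend segment."""
    start = int(fit.breakpoint_years[-1]) if fit.breakpoint_years else int(np.min(years))
    return start, fit.segment_slopes[-1]


def joinpoint_table(panel, max_joinpoints: int = 3):
    """Fit every (country, sex) series in a rate panel; returns a summary frame."""
    import pandas as pd

    rows = []
    for (country, sex), grp in panel.groupby(["country", "sex"], sort=True):
        grp = grp.sort_values("year")
        fit = fit_joinpoint(grp["year"].to_numpy(), grp["asr"].to_numpy(),
                            max_joinpoints=max_joinpoints)
        start, slope = last_segment(fit, grp["year"].to_numpy())
        rows.append({
            "country": country,
            "sex": sex,
            "n_joinpoints": len(fit.breakpoint_years),
            "breakpoint_years": ";".join(str(b) for b in fit.breakpoint_years),
            "last_segment_start": start,
            "last_segment_slope": slope,
            "sse": fit.sse,
            "bic": fit.selection_score,
        })
    return pd.DataFrame(rows)
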
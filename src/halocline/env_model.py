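"""Daily smoothing of sensor series onto the common 3-minute grid.

Raw logger readings (typically every 30 min) are aligned across sensors
by fitting, per calendar day and per variable, a penalized cubic
smoothing spline of value against time of day, with the smoothness
penalty selected by generalized cross-validation, and evaluating the
smooth at 3-minute intervals starting at midnight (480 points per day).
Daily summaries (min/max/mean) and replicate means operate on those
grids.
"""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .types import (
    GRID_MINUTES,
    GRID_N,
    DailyStats,
    GriddedDay,
    SensorSeries,
    VARIABLES,
    variable_column,
)

logger = logging.getLogger(__name__)

#: fewer readings than this and the day cannot be modeled
MIN_READINGS_PER_DAY = 4


class UnmodelableDayError(ValueError):
    """Raised when a day has too few readings to fit a smooth."""


def fit_daily_smooth(
    minutes: Sequence[float], values: Sequence[float], variable: str = "T"
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit the within-day smooth for one variable.

    Parameters are minutes from midnight (within [0, 1440)) and the
    corresponding readings.  Returns a callable defined everywhere on
    [0, 1440).  Smoothness is chosen by GCV; with exactly the minimum
    number of readings a natural interpolating cubic spline is used.
    """
    m = np.asarray(minutes, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(m) & np.isfinite(v)
    m, v = m[keep], v[keep]
    if np.any((m < 0) | (m >= 1440)):
        raise ValueError("minutes must lie within [0, 1440)")
    order = np.argsort(m)
    m, v = m[order], v[order]
    if m.size and np.any(np.diff(m) == 0):
        # average duplicate time stamps before fitting
        uniq, inv = np.unique(m, return_inverse=True)
        sums = np.bincount(inv, weights=v)
        counts = np.bincount(inv)
        m, v = uniq, sums / counts
    if m.size < MIN_READINGS_PER_DAY:
        raise UnmodelableDayError(
            f"need >= {MIN_READINGS_PER_DAY} readings to model a day, got {m.size}"
        )
    if np.ptp(v) == 0.0:
        c = float(v[0])
        return lambda x: np.full(np.shape(x), c, dtype=float)
    if m.size < 5:  # GCV spline needs >= 5 support points
        return CubicSpline(m, v, bc_type="natural")
    return make_smoothing_spline(m, v)


def grid_series(
    series: SensorSeries, variables: Iterable[str] = VARIABLES
) -> list[GriddedDay]:
    """Model each calendar day of each variable onto the 3-min grid.

    Days with fewer than the minimum number of non-missing readings for
    a variable are omitted with a warning.  RH grids are clipped to
    [0, 100] and PAR grids to >= 0 after smoothing.
    """
    if len(series) == 0:
        raise ValueError("cannot grid an empty sensor series")
    out: list[GriddedDay] = []
    dates = series.data.index.date
    minutes_all = (
        series.data.index.hour * 60.0
        + series.data.index.minute
        + series.data.index.second / 60.0
    )
    for date in sorted(set(dates)):
        day_mask = dates == date
        for var in variables:
            col = variable_column(var)
            vals = series.data.loc[day_mask, col].to_numpy()
            mins = np.asarray(minutes_all[day_mask], dtype=float)
            ok = np.isfinite(vals)
            try:
                smooth = fit_daily_smooth(mins[ok], vals[ok], var)
            except UnmodelableDayError:
                logger.warning(
                    "skipping %s %s/%s/%s on %s: %d usable readings (< %d)",
                    var, series.site, series.position, series.replicate,
                    date, int(ok.sum()), MIN_READINGS_PER_DAY,
                )
                continue
            grid = np.asarray(smooth(GRID_MINUTES), dtype=float)
            if var == "RH":
                grid = np.clip(grid, 0.0, 100.0)
            elif var == "PAR":
                grid = np.clip(grid, 0.0, None)
            out.append(
                GriddedDay(
                    date=date, variable=var, values=grid,
                    site=series.site, position=series.position,
                    replicate=series.replicate,
                )
            )
    return out


def daily_stats(grids: Iterable[GriddedDay]) -> DailyStats:
    """Min/max/mean per variable over one day's grids."""
    grids = list(grids)
    if not grids:
        raise ValueError("daily_stats needs at least one grid")
    date = grids[0].date
    if any(g.date != date for g in grids):
        raise ValueError("all grids passed to daily_stats must share a date")
    stats: dict[str, dict[str, float]] = {}
    for g in grids:
        stats[g.variable] = {
            "min": float(np.min(g.values)),
            "max": float(np.max(g.values)),
            "mean": float(np.mean(g.values)),
        }
    return DailyStats(date=date, stats=stats)


def mean_across_replicates(grids: Sequence[GriddedDay]) -> GriddedDay:
    """Pointwise mean of replicate grids for the same site/position/date."""
    if len(grids) == 0:
        raise ValueError("no replicate grids for this day")
    first = grids[0]
    for g in grids[1:]:
        if g.date != first.date or g.variable != first.variable:
            raise ValueError("replicate grids must share date and variable")
    stack = np.stack([g.values for g in grids])
    # identical replicates average to themselves exactly
    mean = stack[0].copy() if (stack == stack[0]).all() else np.mean(stack, axis=0)
    return GriddedDay(
        date=first.date,
        variable=first.variable,
        values=mean,
        site=first.site,
        position=first.position,
        replicate=f"mean_of_{len(grids)}",
    )


def raw_daily_stats(series: SensorSeries) -> list[DailyStats]:
    """Min/max/mean per variable per day from the raw readings.

    Companion to the modeled path (``grid_series`` + ``daily_stats``):
    threshold day-counts can be computed on either, and the two can be
    compared to gauge the effect of smoothing on daily extrema.
    """
    if len(series) == 0:
        raise ValueError("empty sensor series")
    out: list[DailyStats] = []
    for date, day in series.data.groupby(series.data.index.date):
        stats: dict[str, dict[str, float]] = {}
        for var in VARIABLES:
            vals = day[variable_column(var)].dropna()
            if len(vals):
                stats[var] = {
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "mean": float(vals.mean()),
                }
        out.append(DailyStats(date=date, stats=stats))
    return out


def grids_by_day(grids: Iterable[GriddedDay]) -> dict[_dt.date, list[GriddedDay]]:
    """Group grids by calendar date (convenience for daily summaries)."""
    out: dict[_dt.date, list[GriddedDay]] = {}
    for g in grids:
        out.setdefault(g.date, []).append(g)
    return dict(sorted(out.items()))
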
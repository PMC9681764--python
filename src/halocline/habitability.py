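"""Wet and wet+light habitability windows from gridded microclimate.

A 3-minute grid point is "wet" when RH meets the wetting threshold
(deliquescence RH of a saturated NaCl brine, 75 %, inside nodules;
95 % in the air) and "lit" when PAR meets the minimal-photosynthesis
threshold.  Each qualifying point contributes exactly 0.05 h; no
interpolation of crossing times is performed.  Wet/dry period
segmentation classifies days by their wet hours and merges runs shorter
than a minimum length into the enclosing state.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Sequence

import numpy as np

from .types import (
    GRID_N,
    HOURS_PER_POINT,
    DailyStats,
    GriddedDay,
    HabitabilityDay,
    Thresholds,
    WetPeriod,
)


def _meets(values: np.ndarray, threshold: float, strict: bool) -> np.ndarray:
    return values > threshold if strict else values >= threshold


def wet_hours(rh_grid: GriddedDay, threshold: float, strict: bool = False) -> float:
    """Cumulative wet hours of one day: qualifying grid points x 0.05 h."""
    if rh_grid.values.shape != (GRID_N,):
        raise ValueError(f"expected a {GRID_N}-point grid")
    return float(np.count_nonzero(_meets(rh_grid.values, threshold, strict))) * HOURS_PER_POINT


def wetlight_hours(
    rh_grid: GriddedDay,
    par_grid: GriddedDay,
    thresholds: Thresholds = Thresholds(),
    rh_threshold: float | None = None,
) -> float:
    """Cumulative hours with wet AND lit conditions co-occurring.

    The RH threshold defaults to the position-appropriate one (air vs
    halite interior) from ``thresholds``; pass ``rh_threshold`` to
    override.
    """
    if rh_grid.date != par_grid.date:
        raise ValueError(
            f"RH grid is for {rh_grid.date} but PAR grid is for {par_grid.date}"
        )
    if rh_grid.values.shape != (GRID_N,) or par_grid.values.shape != (GRID_N,):
        raise ValueError(f"expected {GRID_N}-point grids")
    th_rh = (
        thresholds.rh_threshold_for(rh_grid.position)
        if rh_threshold is None
        else rh_threshold
    )
    strict = thresholds.strict_inequality
    both = _meets(rh_grid.values, th_rh, strict) & _meets(
        par_grid.values, thresholds.par_light, strict
    )
    return float(np.count_nonzero(both)) * HOURS_PER_POINT


def habitability_day(
    rh_grid: GriddedDay,
    par_grid: GriddedDay | None,
    thresholds: Thresholds = Thresholds(),
) -> HabitabilityDay:
    """Daily wet / wet+light summary for one position's grids."""
    th_rh = thresholds.rh_threshold_for(rh_grid.position)
    wet = wet_hours(rh_grid, th_rh, thresholds.strict_inequality)
    if par_grid is None:
        wl = 0.0
    else:
        wl = wetlight_hours(rh_grid, par_grid, thresholds)
    return HabitabilityDay(date=rh_grid.date, wet_hours=wet, wetlight_hours=wl)


def count_days_above(
    stats: Sequence[DailyStats], variable: str, stat: str, threshold: float,
    strict: bool = False,
) -> int:
    """Number of days whose daily statistic meets the threshold."""
    if not stats:
        raise ValueError("empty daily-stats list")
    vals = np.array([s.get(variable, stat) for s in stats])
    return int(np.count_nonzero(_meets(vals, threshold, strict)))


def _runs(states: Sequence[bool]) -> list[list]:
    runs: list[list] = []
    for s in states:
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([s, 1])
    return runs


def segment_wet_periods(
    hab_days: Sequence[HabitabilityDay],
    wet_day_min_hours: float = 1.0,
    min_run_days: int = 7,
) -> list[WetPeriod]:
    """Partition the record into alternating wet and dry periods.

    A day is wet iff its wet hours reach ``wet_day_min_hours``.  Runs
    shorter than ``min_run_days`` are iteratively absorbed into the
    surrounding state (shortest first, leftmost on ties), so brief
    excursions do not fragment the record.  The returned periods tile
    the record without gaps or overlap.
    """
    if not hab_days:
        raise ValueError("no habitability days to segment")
    days = sorted(hab_days, key=lambda d: d.date)
    for a, b in zip(days, days[1:]):
        gap = (b.date - a.date).days
        if gap != 1:
            raise ValueError(
                f"date gap between {a.date} and {b.date}: fill or split the "
                "record before segmenting"
            )
    states = [d.wet_hours >= wet_day_min_hours for d in days]
    runs = _runs(states)
    while len(runs) > 1:
        short = [i for i, (_, ln) in enumerate(runs) if ln < min_run_days]
        if not short:
            break
        i = min(short, key=lambda i: runs[i][1])
        runs[i][0] = not runs[i][0]  # absorb into the enclosing state
        merged: list[list] = []
        for s, ln in runs:
            if merged and merged[-1][0] == s:
                merged[-1][1] += ln
            else:
                merged.append([s, ln])
        runs = merged
    periods: list[WetPeriod] = []
    pos = 0
    for s, ln in runs:
        periods.append(
            WetPeriod(
                start=days[pos].date,
                end=days[pos + ln - 1].date,
                kind="wet" if s else "dry",
                length_days=ln,
            )
        )
        pos += ln
    return periods
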
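"""Core domain containers shared across the pipeline.

The pipeline moves sensor-logger records (temperature, relative humidity,
photosynthetically active radiation) through a daily smoothing/gridding
stage onto a common 3-minute grid, converts the grids into daily
habitability summaries, and couples them with community abundance tables
and predicted proteomes.  The small dataclasses here are the interchange
currency between those stages.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: grid spacing in minutes and number of grid points per (half-open) day
GRID_STEP_MIN = 3
GRID_N = 1440 // GRID_STEP_MIN  # 480
#: grid abscissae: minutes from midnight, 0, 3, ..., 1437
GRID_MINUTES = np.arange(0, 1440, GRID_STEP_MIN, dtype=float)
#: hours contributed by one grid point
HOURS_PER_POINT = GRID_STEP_MIN / 60.0  # 0.05 h

VARIABLES = ("T", "RH", "PAR")
POSITIONS = ("air", "top", "middle", "bottom")

#: canonical sensor-table column names
SENSOR_COLUMNS = ("timestamp", "temp_c", "rh_pct", "par_umol")
_VAR_TO_COLUMN = {"T": "temp_c", "RH": "rh_pct", "PAR": "par_umol"}


def variable_column(variable: str) -> str:
    """Map a variable code (T/RH/PAR) to its sensor-table column name."""
    try:
        return _VAR_TO_COLUMN[variable]
    except KeyError:
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")


@dataclass
class SensorSeries:
    """Timestamped T/RH/PAR readings for one site/position/replicate.

    ``data`` is a DataFrame indexed by timestamp with columns
    ``temp_c``, ``rh_pct``, ``par_umol``; any variable may be missing
    (NaN) for individual readings.
    """

    site: str
    position: str
    replicate: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}, got {self.position!r}")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("SensorSeries.data must be indexed by timestamps")
        if len(self.data) and not self.data.index.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(self.data) and self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        rh = self.data.get("rh_pct")
        if rh is not None and ((rh.dropna() < 0) | (rh.dropna() > 100)).any():
            raise ValueError("rh_pct outside [0, 100]")
        par = self.data.get("par_umol")
        if par is not None and (par.dropna() < 0).any():
            raise ValueError("par_umol must be >= 0")

    @property
    def dates(self) -> list[_dt.date]:
        return sorted(set(self.data.index.date))

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GriddedDay:
    """Modeled values of one variable on the 3-min grid of one day."""

    date: _dt.date
    variable: str
    values: np.ndarray
    site: str = ""
    position: str = "air"
    replicate: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_N,):
            raise ValueError(f"grid must have exactly {GRID_N} values, got {self.values.shape}")
        if self.variable not in VARIABLES:
            raise ValueError(f"variable must be one of {VARIABLES}")
        if self.variable == "RH" and (np.any(self.values < 0) or np.any(self.values > 100)):
            raise ValueError("RH grid outside [0, 100]")
        if self.variable == "PAR" and np.any(self.values < 0):
            raise ValueError("PAR grid must be >= 0")


@dataclass
class DailyStats:
    """Per-day min/max/mean of each gridded variable."""

    date: _dt.date
    stats: Mapping[str, Mapping[str, float]]  # variable -> {min,max,mean}

    def get(self, variable: str, stat: str) -> float:
        if variable not in self.stats:
            raise ValueError(f"variable {variable!r} not present for {self.date}")
        if stat not in ("min", "max", "mean"):
            raise ValueError(f"stat must be min/max/mean, got {stat!r}")
        return self.stats[variable][stat]


@dataclass(frozen=True)
class Thresholds:
    """Wetness/light thresholds for habitability windows.

    Interior (halite) wetness uses the equilibrium relative humidity of a
    saturated NaCl brine (75 %RH, the deliquescence point); air wetness
    uses 95 %RH (fog/dew collection can occur slightly below saturation);
    light uses the minimum irradiance usable by highly adapted primary
    producers.  Comparison is inclusive (>=) by default;
    ``strict_inequality`` switches to strict (>).
    """

    rh_halite_wet: float = 75.0
    rh_air_wet: float = 95.0
    par_light: float = 0.01
    strict_inequality: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.rh_halite_wet < 100 and 0 < self.rh_air_wet < 100):
            raise ValueError("RH thresholds must lie in (0, 100)")
        if self.par_light <= 0:
            raise ValueError("PAR threshold must be > 0")

    def rh_threshold_for(self, position: str) -> float:
        """Air positions use the air-wetting threshold, interior the deliquescence one."""
        return self.rh_air_wet if position == "air" else self.rh_halite_wet


@dataclass
class HabitabilityDay:
    """Cumulative daily wet and wet+light hours."""

    date: _dt.date
    wet_hours: float
    wetlight_hours: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.wetlight_hours <= self.wet_hours <= 24.0 + 1e-12):
            raise ValueError(
                f"need 0 <= wetlight ({self.wetlight_hours}) <= wet ({self.wet_hours}) <= 24"
            )


@dataclass
class WetPeriod:
    """A maximal run of consecutive wet (or dry) days."""

    start: _dt.date
    end: _dt.date
    kind: str  # "wet" | "dry"
    length_days: int

    def __post_init__(self) -> None:
        if self.kind not in ("wet", "dry"):
            raise ValueError("kind must be 'wet' or 'dry'")
        if self.length_days < 1 or (self.end - self.start).days + 1 != self.length_days:
            raise ValueError("length_days must match the [start, end] span")


@dataclass
class AbundanceTable:
    """Feature x sample relative abundances (%) with taxonomy and site labels.

    ``values``: DataFrame (features x samples), each column summing to 100.
    ``sites``: sample id -> site label.
    ``taxonomy``: optional DataFrame indexed by feature with columns
    ``domain``, ``phylum`` (and optionally ``genus``).
    """

    values: pd.DataFrame
    sites: Mapping[str, str]
    taxonomy: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.values.values < -1e-12).any():
            raise ValueError("abundances must be non-negative")
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 100.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 100.0, atol=1e-6)].index.tolist()
            raise ValueError(f"columns must sum to 100%: offending samples {bad}")
        missing = [s for s in self.values.columns if s not in self.sites]
        if missing:
            raise ValueError(f"samples without site labels: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def site_of(self, sample: str) -> str:
        return self.sites[sample]

    def samples_by_site(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(self.sites[s], []).append(s)
        return out

    def site_means(self) -> pd.DataFrame:
        """Mean relative abundance per feature per site (features x sites)."""
        groups = self.samples_by_site()
        return pd.DataFrame(
            {site: self.values[cols].mean(axis=1) for site, cols in groups.items()}
        )


@dataclass(frozen=True)
class MAGRecord:
    """Quality record for one metagenome-assembled genome."""

    id: str
    completeness: float
    contamination: float
    taxonomy: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"completeness must be in [0, 100], got {self.completeness}")
        if self.contamination < 0:
            raise ValueError(f"contamination must be >= 0, got {self.contamination}")

    @property
    def quality_score(self) -> float:
        """Dereplication representative score: completeness − 5·contamination."""
        return self.completeness - 5.0 * self.contamination


@dataclass
class ProteinRecord:
    """Predicted protein with the abundance weight of its source contig."""

    id: str
    contig: str
    sequence: str
    weight: float = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        if self.weight < 0:
            raise ValueError(f"protein {self.id!r} has negative weight")


def make_sensor_frame(
    timestamps: Iterable,
    temp_c: Optional[Iterable[float]] = None,
    rh_pct: Optional[Iterable[float]] = None,
    par_umol: Optional[Iterable[float]] = None,
) -> pd.DataFrame:
    """Assemble a canonical sensor DataFrame from column arrays."""
    idx = pd.DatetimeIndex(pd.to_datetime(list(timestamps)))
    n = len(idx)

    def col(x):
        return np.full(n, np.nan) if x is None else np.asarray(list(x), dtype=float)

    return pd.DataFrame(
        {"temp_c": col(temp_c), "rh_pct": col(rh_pct), "par_umol": col(par_umol)},
        index=idx,
    )
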
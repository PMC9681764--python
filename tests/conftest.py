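"""Shared fixtures: deterministic microclimate regimes and small tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from halocline.synthetic import (
    AirClimateParams,
    BrineParams,
    simulate_air_series,
    simulate_nodule_series,
)
from halocline.types import GRID_MINUTES, AbundanceTable, GriddedDay


def dry_air_params(record_days: int, rain_days=(), seed: int = 0) -> AirClimateParams:
    """Noise-free air regime that never reaches the deliquescence RH
    except on forced rain days (envelope 20-60 %RH)."""
    return AirClimateParams(
        record_days=record_days,
        rh_mean=40.0,
        rh_amplitude=20.0,
        fog_prob_per_night=0.0,
        noise_sd_t=0.0,
        noise_sd_rh=0.0,
        rain_days=tuple(rain_days),
        seed=seed,
    )


@pytest.fixture(scope="session")
def alma_fixture():
    """Cycling regime: initial brine plus two isolated rain recharges.

    The reservoir drains in ~25 days; rain blocks at days 45-46 and
    100-101 recharge it, and the record ends while the third wet spell
    is still running, so the record splits into exactly three wet and
    two dry periods.
    """
    air = simulate_air_series(
        dry_air_params(120, rain_days=(45, 46, 100, 101)), site="alma_like"
    )
    brine = BrineParams(
        initial_reservoir=0.9,
        recharge_rate=0.03,
        evaporation_rate=1.0 / (25 * 24),
        interior_noise_sd=0.0,
        relaxation_halflife_h=6.0,
    )
    nodule = simulate_nodule_series(air, brine, position="top", seed=1)
    return air, brine, nodule


@pytest.fixture(scope="session")
def progressive_dry_fixture():
    """Drying regime: a modest initial reservoir, no recharge, so the
    interior dries out monotonically (noise-free)."""
    air = simulate_air_series(dry_air_params(60), site="yungay_like")
    brine = BrineParams(
        initial_reservoir=0.5,
        recharge_rate=0.0,
        evaporation_rate=1.0 / (30 * 24),
        interior_noise_sd=0.0,
        relaxation_halflife_h=12.0,
    )
    nodule = simulate_nodule_series(air, brine, position="top", seed=2)
    return air, brine, nodule


def constant_grid(value: float, variable: str = "RH", **meta) -> GriddedDay:
    import datetime

    return GriddedDay(
        date=meta.pop("date", datetime.date(2018, 3, 1)),
        variable=variable,
        values=np.full(len(GRID_MINUTES), float(value)),
        **meta,
    )


@pytest.fixture
def toy_table() -> AbundanceTable:
    """Three-site toy abundance table with archaeal/bacterial taxonomy."""
    values = pd.DataFrame(
        {
            "s1_a": [50.0, 30.0, 20.0],
            "s1_b": [40.0, 35.0, 25.0],
            "s2_a": [80.0, 10.0, 10.0],
            "s2_b": [70.0, 20.0, 10.0],
            "s3_a": [20.0, 60.0, 20.0],
            "s3_b": [30.0, 50.0, 20.0],
        },
        index=["arch1", "bact1", "bact2"],
    )
    sites = {s: s.split("_")[0] for s in values.columns}
    taxonomy = pd.DataFrame(
        {
            "domain": ["Archaea", "Bacteria", "Bacteria"],
            "phylum": ["Euryarchaeota", "Bacteroidetes", "Cyanobacteria"],
        },
        index=values.index,
    )
    return AbundanceTable(values=values, sites=sites, taxonomy=taxonomy)
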
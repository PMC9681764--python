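"""Synthetic microclimate, community, and proteome generators.

These emulate the study conditions of a halite-nodule transplant
experiment in a hyper-arid desert: contrasting diurnal air temperature /
relative humidity / PAR regimes with fog nights and occasional rain, an
interior ("nodule") humidity buffered at the NaCl deliquescence point
(~75 %RH) while a brine reservoir persists, community abundance tables
in which salt-in strategist taxa gain under dryness, and proteomes with
a tunable acidic-residue bias (the salt-in proteome signature).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import AbundanceTable, ProteinRecord, SensorSeries, make_sensor_frame

# default record start (the field deployment season); arbitrary but fixed
DEFAULT_START = _dt.datetime(2018, 2, 15)


# --------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class AirClimateParams:
    """Diurnal air-climate regime of one site.

    Temperature is a diurnal sinusoid peaking mid-afternoon; RH is
    anti-phased with temperature; fog nights lift RH toward
    ``fog_rh_peak`` between 00:00 and 08:00; rain days force RH >= 99
    for the whole day; PAR is a daylight half-sine scaled by
    ``par_peak``.
    """

    record_days: int = 365
    t_mean: float = 18.0
    t_amplitude: float = 8.0
    rh_mean: float = 55.0
    rh_amplitude: float = 30.0
    fog_prob_per_night: float = 0.2
    fog_rh_peak: float = 97.0
    rain_days: tuple[int, ...] = ()
    noise_sd_t: float = 0.3
    noise_sd_rh: float = 1.5
    par_peak: float = 2000.0
    sampling_interval_min: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.record_days < 1:
            raise ValueError("record_days must be >= 1")
        if 1440 % self.sampling_interval_min != 0:
            raise ValueError("sampling_interval_min must divide 1440")
        if not 0.0 <= self.fog_prob_per_night <= 1.0:
            raise ValueError("fog_prob_per_night must be a probability")
        for d in self.rain_days:
            if not 0 <= d < self.record_days:
                raise ValueError(
                    f"rain day index {d} outside record [0, {self.record_days})"
                )


@dataclass(frozen=True)
class BrineParams:
    """Bucket model of the brine reservoir inside a halite nodule.

    The reservoir (dimensionless, in [0, 1]) recharges while the outside
    air is at or above the deliquescence RH and evaporates otherwise.
    While brine persists the interior RH sits at the deliquescence point
    (+ sensor noise); once exhausted it relaxes exponentially toward the
    ambient air RH.
    """

    initial_reservoir: float = 1.0
    recharge_rate: float = 0.05  # reservoir units / hour while air is wet
    evaporation_rate: float = 0.0008  # reservoir units / hour while air is dry
    deliquescence_rh: float = 75.0
    interior_noise_sd: float = 0.0
    relaxation_halflife_h: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_reservoir <= 1.0:
            raise ValueError("initial_reservoir must be in [0, 1]")
        if min(self.recharge_rate, self.evaporation_rate, self.interior_noise_sd) < 0:
            raise ValueError("rates and noise must be >= 0")
        if not 0.0 < self.deliquescence_rh < 100.0:
            raise ValueError("deliquescence_rh must be in (0, 100)")
        if self.relaxation_halflife_h <= 0:
            raise ValueError("relaxation_halflife_h must be > 0")


@dataclass(frozen=True)
class CommunitySimParams:
    """Dirichlet community simulator with a dryness-coupled salt-in effect."""

    n_taxa: int = 40
    salt_in_fraction: float = 0.3
    dryness_sensitivity: float = 2.0
    dirichlet_concentration: float = 50.0
    n_replicates_per_site: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0.0 <= self.salt_in_fraction <= 1.0:
            raise ValueError("salt_in_fraction must be in [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.n_replicates_per_site < 1:
            raise ValueError("n_replicates_per_site must be >= 1")


@dataclass(frozen=True)
class ProteomeSimParams:
    """Random proteome with an optional acidic (D/E) compositional bias."""

    n_proteins: int = 300
    length_range: tuple[int, int] = (80, 400)
    acidic_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length_range must satisfy 10 <= lo <= hi")
        if self.acidic_bias < 0:
            raise ValueError("acidic_bias must be >= 0")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


# --------------------------------------------------------------------------
# microclimate


def _minutes_of_day(n_days: int, interval: int) -> tuple[np.ndarray, np.ndarray]:
    per_day = 1440 // interval
    m = np.tile(np.arange(0, 1440, interval, dtype=float), n_days)
    day = np.repeat(np.arange(n_days), per_day)
    return m, day


#: shape of the nocturnal fog RH lift (higher = narrower saturated spell)
FOG_BUMP_EXPONENT = 6.0


def simulate_air_series(
    params: AirClimateParams,
    site: str = "synthetic",
    start: _dt.datetime = DEFAULT_START,
) -> SensorSeries:
    """Simulate an air T/RH/PAR logger record for one site.

    Fog nights are drawn per night with ``fog_prob_per_night``; on a fog
    night RH is lifted toward ``fog_rh_peak`` by a half-sine bump over
    00:00-08:00 (peaking 04:00).  Rain days force RH >= 99 for the whole
    day.  PAR is a noiseless daylight half-sine (06:00-18:00).
    """
    rng = np.random.default_rng(params.seed)
    m, day = _minutes_of_day(params.record_days, params.sampling_interval_min)
    n = m.size

    phase = 2.0 * np.pi * (m - 540.0) / 1440.0  # sin peaks at 15:00
    temp = params.t_mean + params.t_amplitude * np.sin(phase)
    rh = params.rh_mean - params.rh_amplitude * np.sin(phase)

    # nocturnal fog: sharp pre-dawn lift toward fog_rh_peak over 00:00-08:00
    # (peaking 04:00; the exponent keeps the saturated spell short, as for
    # radiation fog)
    fog_nights = rng.random(params.record_days) < params.fog_prob_per_night
    bump = np.where(m < 480.0, np.sin(np.pi * m / 480.0), 0.0) ** FOG_BUMP_EXPONENT
    lift = fog_nights[day] * bump
    rh = rh + lift * np.clip(params.fog_rh_peak - rh, 0.0, None)

    temp = temp + rng.normal(0.0, params.noise_sd_t, n)
    rh = rh + rng.normal(0.0, params.noise_sd_rh, n)

    # rain: contiguous forced-saturation block covering the whole rain day
    for d in params.rain_days:
        rh[day == d] = 99.5

    par = params.par_peak * np.where(
        (m >= 360.0) & (m < 1080.0), np.sin(np.pi * (m - 360.0) / 720.0), 0.0
    )

    rh = np.clip(rh, 0.0, 100.0)
    par = np.clip(par, 0.0, None)

    timestamps = start + pd.to_timedelta(
        day * 1440 + m, unit="m"
    )
    frame = make_sensor_frame(timestamps, temp, rh, par)
    return SensorSeries(site=site, position="air", replicate="air", data=frame)


#: fraction of ambient PAR reaching the top colonization zone of a nodule
TOP_PAR_ATTENUATION = 0.01


def simulate_nodule_series(
    air: SensorSeries,
    params: BrineParams,
    position: str = "top",
    replicate: str = "n1",
    seed: int = 0,
) -> SensorSeries:
    """Run the brine bucket model against an air record.

    Per time step the reservoir gains ``recharge_rate``·dt when the air
    RH is at/above the deliquescence point and loses
    ``evaporation_rate``·dt otherwise (clamped to [0, 1]).  Interior RH
    equals the deliquescence RH (+ noise) while the reservoir holds
    brine, and otherwise decays exponentially toward the current air RH
    with the configured half-life.  Interior temperature copies air
    temperature; interior PAR is zero except a fixed attenuation of air
    PAR at the top position.
    """
    if position not in ("top", "middle", "bottom"):
        raise ValueError("position must be top, middle, or bottom")
    idx = air.data.index
    if len(idx) < 2:
        raise ValueError("air series must contain at least two readings")
    steps_h = np.diff(idx.values).astype("timedelta64[s]").astype(float) / 3600.0
    if np.any(steps_h <= 0):
        raise ValueError("air series timestamps must be strictly increasing")

    rng = np.random.default_rng(seed)
    air_rh = air.data["rh_pct"].to_numpy()
    air_t = air.data["temp_c"].to_numpy()
    air_par = air.data["par_umol"].to_numpy()
    n = len(idx)

    reservoir = params.initial_reservoir
    rh_int = np.empty(n)
    decay_state = params.deliquescence_rh  # interior RH carried through dry spells
    wet0 = reservoir > 0.0
    rh_int[0] = params.deliquescence_rh if wet0 else air_rh[0]
    k_ln2 = np.log(2.0)
    for i in range(1, n):
        dt = steps_h[i - 1]
        if air_rh[i] >= params.deliquescence_rh:
            reservoir += params.recharge_rate * dt
        else:
            reservoir -= params.evaporation_rate * dt
        reservoir = min(1.0, max(0.0, reservoir))
        if reservoir > 0.0:
            rh_int[i] = params.deliquescence_rh
            decay_state = params.deliquescence_rh
        else:
            # exponential relaxation toward the current ambient RH
            f = np.exp(-k_ln2 * dt / params.relaxation_halflife_h)
            decay_state = air_rh[i] + (decay_state - air_rh[i]) * f
            rh_int[i] = decay_state
    if params.interior_noise_sd > 0:
        rh_int = rh_int + rng.normal(0.0, params.interior_noise_sd, n)
    rh_int = np.clip(rh_int, 0.0, 100.0)

    par_int = air_par * TOP_PAR_ATTENUATION if position == "top" else np.zeros(n)
    frame = make_sensor_frame(idx, air_t, rh_int, par_int)
    return SensorSeries(site=air.site, position=position, replicate=replicate, data=frame)


# --------------------------------------------------------------------------
# community


_SALT_IN_PHYLA = ("Euryarchaeota",)
_OTHER_PHYLA = ("Cyanobacteria", "Bacteroidetes", "Proteobacteria", "Actinobacteria")


def simulate_community(
    dryness_index_per_site: Mapping[str, float],
    params: CommunitySimParams,
) -> tuple[AbundanceTable, pd.Series]:
    """Draw per-replicate community profiles coupled to site dryness.

    Baseline taxon log-weights are shared across sites; salt-in taxa get
    ``dryness_sensitivity * dryness_index`` added to their log-weight at
    each site.  Replicate profiles are Dirichlet draws around the
    resulting site composition.  Returns the abundance table (% per
    sample) and the ground-truth salt-in flag per taxon.
    """
    for site, d in dryness_index_per_site.items():
        if not np.isfinite(d):
            raise ValueError(f"dryness index for site {site!r} is not finite")
    rng = np.random.default_rng(params.seed)
    taxa = [f"taxon_{i:03d}" for i in range(params.n_taxa)]
    n_salt = int(round(params.salt_in_fraction * params.n_taxa))
    salt_idx = rng.choice(params.n_taxa, size=n_salt, replace=False)
    salt_in = np.zeros(params.n_taxa, dtype=bool)
    salt_in[salt_idx] = True

    base_logw = rng.normal(0.0, 1.0, params.n_taxa)

    columns: dict[str, np.ndarray] = {}
    sites: dict[str, str] = {}
    for site in dryness_index_per_site:
        logw = base_logw + params.dryness_sensitivity * dryness_index_per_site[site] * salt_in
        p = np.exp(logw - logw.max())
        p /= p.sum()
        alpha = params.dirichlet_concentration * p
        for r in range(params.n_replicates_per_site):
            sample = f"{site}_r{r + 1}"
            columns[sample] = rng.dirichlet(alpha) * 100.0
            sites[sample] = site

    values = pd.DataFrame(columns, index=taxa)
    phyla = np.where(
        salt_in,
        _SALT_IN_PHYLA[0],
        [_OTHER_PHYLA[i % len(_OTHER_PHYLA)] for i in range(params.n_taxa)],
    )
    taxonomy = pd.DataFrame(
        {
            "domain": np.where(salt_in, "Archaea", "Bacteria"),
            "phylum": phyla,
        },
        index=taxa,
    )
    table = AbundanceTable(values=values, sites=sites, taxonomy=taxonomy)
    return table, pd.Series(salt_in, index=taxa, name="salt_in")


# --------------------------------------------------------------------------
# proteome

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
# background composition (roughly natural usage frequencies)
_BASE_FREQ = {
    "A": 8.3, "C": 1.4, "D": 5.4, "E": 6.8, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 6.0, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 4.0,
    "R": 5.5, "S": 6.6, "T": 5.3, "V": 6.9, "W": 1.1, "Y": 2.9,
}


def proteome_composition(acidic_bias: float) -> np.ndarray:
    """Residue sampling probabilities with D/E over-weighted by (1 + bias)."""
    freq = np.array([_BASE_FREQ[a] for a in AMINO_ACIDS])
    for aa in ("D", "E"):
        freq[AMINO_ACIDS.index(aa)] *= 1.0 + acidic_bias
    return freq / freq.sum()


def simulate_proteome(params: ProteomeSimParams) -> list[ProteinRecord]:
    """Draw random protein sequences with uniform abundance weights."""
    rng = np.random.default_rng(params.seed)
    p = proteome_composition(params.acidic_bias)
    lo, hi = params.length_range
    lengths = rng.integers(lo, hi + 1, params.n_proteins)
    letters = np.array(AMINO_ACIDS)
    records = []
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(letters, size=int(L), p=p))
        records.append(
            ProteinRecord(id=f"contig{i:05d}_1", contig=f"contig{i:05d}", sequence=seq)
        )
    return records


# --------------------------------------------------------------------------
# site regime presets

#: dryness index used to couple the community simulator to the sites
SITE_DRYNESS = {
    "salar_grande": 0.0,
    "chanaral": 0.05,
    "yungay": 0.6,
    "alma": 1.0,
}


def site_regime(
    site: str, record_days: int = 365, seed: int = 0
) -> tuple[AirClimateParams, BrineParams]:
    """Default air + brine parameterizations for the four study-site regimes.

    ``salar_grande`` and ``chanaral``: coastal fog-fed regimes whose
    nodules stay brine-filled (interior RH pinned near 75 % throughout).
    ``alma``: high, dry, cold regime with three rain events that drive
    wet/dry cycling of the reservoir.  ``yungay``: dry regime with no
    recharge, so the nodules progressively dry out.
    """
    scale = record_days / 365.0

    def rain(days: Sequence[int]) -> tuple[int, ...]:
        return tuple(int(d * scale) for d in days if int(d * scale) < record_days)

    if site == "salar_grande":
        air = AirClimateParams(
            record_days=record_days, t_mean=20.0, t_amplitude=8.0,
            rh_mean=55.0, rh_amplitude=30.0, fog_prob_per_night=85 / 365,
            fog_rh_peak=97.0, seed=seed,
        )
        brine = BrineParams(initial_reservoir=1.0, recharge_rate=0.05,
                            evaporation_rate=0.0003)
    elif site == "chanaral":
        air = AirClimateParams(
            record_days=record_days, t_mean=17.0, t_amplitude=7.0,
            rh_mean=60.0, rh_amplitude=28.0, fog_prob_per_night=239 / 365,
            fog_rh_peak=97.0, seed=seed,
        )
        brine = BrineParams(initial_reservoir=1.0, recharge_rate=0.05,
                            evaporation_rate=0.0003)
    elif site == "alma":
        air = AirClimateParams(
            record_days=record_days, t_mean=8.0, t_amplitude=10.0,
            rh_mean=28.0, rh_amplitude=18.0, fog_prob_per_night=15 / 365,
            fog_rh_peak=96.0,
            rain_days=rain((10, 11, 12, 160, 161, 162, 280, 281, 282)),
            seed=seed,
        )
        # reservoir drains in ~55 dry days; a three-day rain event refills
        # it, while a single fog night adds only a couple of wet days
        brine = BrineParams(initial_reservoir=1.0, recharge_rate=0.015,
                            evaporation_rate=0.00076)
    elif site == "yungay":
        air = AirClimateParams(
            record_days=record_days, t_mean=18.0, t_amplitude=12.0,
            rh_mean=45.0, rh_amplitude=25.0, fog_prob_per_night=16 / 365,
            fog_rh_peak=96.0, seed=seed,
        )
        # no effective recharge: progressive drying over ~120 days
        brine = BrineParams(initial_reservoir=0.8, recharge_rate=0.0,
                            evaporation_rate=0.00028)
    else:
        raise ValueError(
            f"unknown site regime {site!r}; expected one of {sorted(SITE_DRYNESS)}"
        )
    return air, brine
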
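"""Generators: determinism, regime construction, and bucket-model behavior."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from halocline.synthetic import (
    AirClimateParams,
    BrineParams,
    CommunitySimParams,
    ProteomeSimParams,
    simulate_air_series,
    simulate_community,
    simulate_nodule_series,
    simulate_proteome,
    site_regime,
)
from halocline import proteome as prot

from conftest import dry_air_params


def daily_max_rh(series) -> pd.Series:
    rh = series.data["rh_pct"]
    return rh.groupby(series.data.index.date).max()


class TestAirSeries:
    def test_forced_fog_every_night_pushes_daily_max_over_95(self):
        p = AirClimateParams(
            record_days=10, fog_prob_per_night=1.0, fog_rh_peak=99.0,
            noise_sd_rh=0.5, seed=11,
        )
        air = simulate_air_series(p)
        assert (daily_max_rh(air) >= 95.0).all()

    def test_dry_regime_never_reaches_95(self):
        p = AirClimateParams(
            record_days=10, fog_prob_per_night=0.0, rh_mean=40.0,
            rh_amplitude=10.0, noise_sd_rh=0.0, seed=0,
        )
        air = simulate_air_series(p)
        assert (daily_max_rh(air) < 95.0).all()

    def test_same_seed_reproduces_series_exactly(self):
        p = AirClimateParams(record_days=5, seed=42)
        a = simulate_air_series(p)
        b = simulate_air_series(p)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_cadence_and_ranges(self):
        p = AirClimateParams(record_days=3, sampling_interval_min=30, seed=1)
        air = simulate_air_series(p)
        assert len(air) == 3 * 48
        assert air.data["rh_pct"].between(0, 100).all()
        assert (air.data["par_umol"] >= 0).all()
        # PAR dark at night, bright midday
        m = air.data.index.hour * 60 + air.data.index.minute
        assert (air.data["par_umol"][(m < 360) | (m >= 1080)] == 0).all()

    def test_rain_day_out_of_record_is_rejected_by_index(self):
        with pytest.raises(ValueError, match="7"):
            AirClimateParams(record_days=5, rain_days=(7,))


class TestNoduleBucket:
    def test_no_evaporation_keeps_interior_at_deliquescence(self):
        air = simulate_air_series(dry_air_params(5))
        brine = BrineParams(initial_reservoir=1.0, evaporation_rate=0.0,
                            interior_noise_sd=0.0)
        nod = simulate_nodule_series(air, brine)
        assert np.allclose(nod.data["rh_pct"], brine.deliquescence_rh)

    def test_no_recharge_relaxes_toward_air_and_stays_low(self):
        air = simulate_air_series(dry_air_params(20))
        brine = BrineParams(initial_reservoir=0.02, recharge_rate=0.0,
                            evaporation_rate=0.01, interior_noise_sd=0.0)
        nod = simulate_nodule_series(air, brine)
        rh = nod.data["rh_pct"].to_numpy()
        assert rh[0] == brine.deliquescence_rh
        assert (rh[-48 * 5:] < 65).all()  # converged toward the dry air

    def test_two_rain_blocks_give_two_returns_matching_bucket_recursion(self):
        air = simulate_air_series(dry_air_params(40, rain_days=(15, 30)))
        brine = BrineParams(initial_reservoir=0.2, recharge_rate=0.05,
                            evaporation_rate=0.01, interior_noise_sd=0.0,
                            relaxation_halflife_h=6.0)
        nod = simulate_nodule_series(air, brine)
        rh = nod.data["rh_pct"].to_numpy()

        # independent step-by-step bucket recursion on the known air input
        air_rh = air.data["rh_pct"].to_numpy()
        dt = 0.5
        res = brine.initial_reservoir
        expect = [brine.deliquescence_rh]
        state = brine.deliquescence_rh
        for i in range(1, air_rh.size):
            if air_rh[i] >= brine.deliquescence_rh:
                res = min(1.0, res + brine.recharge_rate * dt)
            else:
                res = max(0.0, res - brine.evaporation_rate * dt)
            if res > 0:
                state = brine.deliquescence_rh
                expect.append(brine.deliquescence_rh)
            else:
                f = np.exp(-np.log(2) * dt / brine.relaxation_halflife_h)
                state = air_rh[i] + (state - air_rh[i]) * f
                expect.append(state)
        assert np.allclose(rh, expect, atol=1e-9)

        # at least two distinct returns to the deliquescence plateau,
        # separated by spells well below it
        at75 = rh >= brine.deliquescence_rh - 1e-9
        transitions = np.flatnonzero(np.diff(at75.astype(int)) == 1)
        assert len(transitions) >= 2
        assert rh.min() < 50

    def test_interior_rh_bounded_and_temperature_copied(self):
        air = simulate_air_series(dry_air_params(10, rain_days=(4,)))
        nod = simulate_nodule_series(air, BrineParams(interior_noise_sd=3.0), seed=7)
        assert nod.data["rh_pct"].between(0, 100).all()
        assert np.allclose(nod.data["temp_c"], air.data["temp_c"])

    def test_par_attenuation_by_position(self):
        air = simulate_air_series(dry_air_params(2))
        top = simulate_nodule_series(air, BrineParams(), position="top")
        mid = simulate_nodule_series(air, BrineParams(), position="middle")
        assert np.allclose(top.data["par_umol"], 0.01 * air.data["par_umol"])
        assert (mid.data["par_umol"] == 0).all()

    def test_non_monotone_timestamps_rejected(self):
        air = simulate_air_series(dry_air_params(2))
        shuffled = air.data.iloc[[1, 0] + list(range(2, len(air.data)))]
        import halocline.types as t

        with pytest.raises(ValueError):
            t.SensorSeries("x", "air", "r", shuffled)


class TestCommunitySim:
    def test_samples_sum_to_100(self):
        table, _ = simulate_community({"a": 0.0, "b": 1.0}, CommunitySimParams(seed=3))
        assert np.allclose(table.values.sum(axis=0), 100.0, atol=1e-9 * 100)

    def test_zero_sensitivity_gives_identical_expected_abundances(self):
        params = CommunitySimParams(
            n_taxa=12, dryness_sensitivity=0.0, n_replicates_per_site=400, seed=5
        )
        table, _ = simulate_community({"wet": 0.0, "dry": 1.0}, params)
        means = table.site_means()
        assert np.abs(means["wet"] - means["dry"]).max() < 1.0  # percent

    def test_salt_in_gain_at_driest_site_across_seeds(self):
        wins = 0
        n_runs = 100
        for seed in range(n_runs):
            params = CommunitySimParams(
                n_taxa=20, salt_in_fraction=0.5, dryness_sensitivity=2.0,
                n_replicates_per_site=4, seed=seed,
            )
            table, salt_in = simulate_community({"wet": 0.0, "dry": 1.0}, params)
            tot = table.values.loc[salt_in[salt_in].index].sum(axis=0)
            sites = pd.Series(table.sites)
            if tot[sites == "dry"].mean() > tot[sites == "wet"].mean():
                wins += 1
        assert wins >= 95

    def test_ground_truth_flags_match_taxonomy(self):
        table, salt_in = simulate_community({"a": 0.0}, CommunitySimParams(seed=9))
        dom = table.taxonomy["domain"]
        assert ((dom == "Archaea") == salt_in).all()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            CommunitySimParams(n_taxa=1)


class TestProteomeSim:
    def test_acidic_bias_lowers_weighted_mean_pi(self):
        lo = simulate_proteome(ProteomeSimParams(n_proteins=500, acidic_bias=5.0, seed=4))
        hi = simulate_proteome(ProteomeSimParams(n_proteins=500, acidic_bias=0.0, seed=4))
        assert prot.weighted_mean_pi(lo) < prot.weighted_mean_pi(hi)

    def test_fixed_length_range(self):
        recs = simulate_proteome(ProteomeSimParams(n_proteins=20, length_range=(10, 10), seed=0))
        assert all(len(r.sequence) == 10 for r in recs)

    def test_same_seed_identical_sequences(self):
        a = simulate_proteome(ProteomeSimParams(n_proteins=10, seed=6))
        b = simulate_proteome(ProteomeSimParams(n_proteins=10, seed=6))
        assert [r.sequence for r in a] == [r.sequence for r in b]


def test_site_regimes_are_known():
    for site in ("salar_grande", "chanaral", "yungay", "alma"):
        air, brine = site_regime(site, record_days=30, seed=0)
        assert air.record_days == 30
    with pytest.raises(ValueError):
        site_regime("atlantis")
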
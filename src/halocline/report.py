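"""End-to-end synthetic study: simulate -> grid -> habitability ->
community -> proteome, with a report bundle of TSVs, figures, and
provenance.

The run emulates the four-site halite-nodule transplant design: a
fog-fed control regime (salar_grande), a similar coastal regime
(chanaral), a high/dry/cold regime with three rain-driven wet/dry
cycles (alma), and a progressively drying regime (yungay).  Each stage
writes its tables under the output directory and the headline numbers
are returned as a flat dict.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import community as comm
from . import env_model, habitability as hab, proteome as prot
from .io import RunConfig, config_hash, write_grids, write_table
from .synthetic import (
    SITE_DRYNESS,
    CommunitySimParams,
    ProteomeSimParams,
    simulate_air_series,
    simulate_community,
    simulate_nodule_series,
    simulate_proteome,
    site_regime,
)
from .types import Thresholds

logger = logging.getLogger(__name__)

SITES = tuple(SITE_DRYNESS)  # salar_grande, chanaral, yungay, alma
DRY_SITES = ("alma", "yungay")
WET_SITES = ("salar_grande", "chanaral")


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def run_report(config: RunConfig) -> dict:
    """Run the full synthetic study and emit the report bundle.

    Returns the headline quantities (day counts, wet/dry period counts,
    archaea:bacteria ratios, ANOSIM R/p, weighted mean pI contrast, Trk
    potential) as a flat dict of numbers.
    """
    out = Path(config.out_dir)
    for sub in ("env", "habitability", "community", "proteome", "figures"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()
    prov = {
        "config_hash": config_hash(
            {k: v for k, v in cfg_dict.items() if k != "out_dir"}
        ),
        "seed": config.seed,
    }
    th = config.thresholds
    results: dict[str, float] = {}

    # ---------------- microclimate & habitability ----------------
    hab_rows = []
    period_rows = []
    counter = 0
    for site in SITES:
        air_params, brine = site_regime(
            site, record_days=config.record_days, seed=_sub_seed(config.seed, counter)
        )
        counter += 1
        air = simulate_air_series(air_params, site=site)
        air_rh_grids = env_model.grid_series(air, variables=("RH",))
        stats = [env_model.daily_stats([g]) for g in air_rh_grids]
        results[f"{site}_days_air_rh_max_ge_95"] = hab.count_days_above(
            stats, "RH", "max", th.rh_air_wet, strict=th.strict_inequality
        )

        # replicate nodules, top position carries the light signal
        rep_rh, rep_par = [], []
        for r in range(config.n_sensor_replicates):
            nod = simulate_nodule_series(
                air, brine, position="top", replicate=f"n{r + 1}",
                seed=_sub_seed(config.seed, counter),
            )
            counter += 1
            rep_rh.append(env_model.grid_series(nod, variables=("RH",)))
            rep_par.append(env_model.grid_series(nod, variables=("PAR",)))
        n_days = min(len(g) for g in rep_rh)
        days = []
        for i in range(n_days):
            rh_mean = env_model.mean_across_replicates([g[i] for g in rep_rh])
            par_mean = env_model.mean_across_replicates([g[i] for g in rep_par])
            days.append(hab.habitability_day(rh_mean, par_mean, th))
        for d in days:
            hab_rows.append(
                {"site": site, "position": "top", "date": d.date,
                 "wet_hours": d.wet_hours, "wetlight_hours": d.wetlight_hours}
            )
        periods = hab.segment_wet_periods(
            days, config.wet_day_min_hours, config.min_run_days
        )
        for p in periods:
            period_rows.append(
                {"site": site, "kind": p.kind, "start": p.start, "end": p.end,
                 "length_days": p.length_days}
            )
        results[f"{site}_wet_periods"] = sum(p.kind == "wet" for p in periods)
        results[f"{site}_dry_periods"] = sum(p.kind == "dry" for p in periods)
        results[f"{site}_mean_wet_hours"] = float(
            np.mean([d.wet_hours for d in days])
        )
        if site == "salar_grande":
            write_grids(air_rh_grids[:7], out / "env" / "salar_grande_air_rh_grids.tsv",
                        provenance=prov)

    hab_frame = pd.DataFrame(hab_rows)
    write_table(hab_frame, out / "habitability" / "daily_hours.tsv", prov, index=False)
    write_table(pd.DataFrame(period_rows), out / "habitability" / "wet_periods.tsv",
                prov, index=False)

    # ---------------- community ----------------
    cparams = CommunitySimParams(
        n_taxa=config.n_taxa,
        dryness_sensitivity=config.dryness_sensitivity,
        n_replicates_per_site=config.n_replicates_per_site,
        seed=_sub_seed(config.seed, 9001),
    )
    table, salt_in = simulate_community(SITE_DRYNESS, cparams)
    per_sample_ratio, per_site_ratio = comm.archaea_bacteria_ratio(table)
    for site in SITES:
        results[f"{site}_archaea_bacteria_ratio"] = float(per_site_ratio[site])
    dm = comm.bray_curtis(table)
    ord_res = comm.pcoa(dm)
    grouping = {
        s: ("dry" if table.sites[s] in DRY_SITES else "wet") for s in table.samples
    }
    an = comm.anosim(
        dm, grouping, n_permutations=config.n_permutations,
        seed=_sub_seed(config.seed, 9002),
    )
    results["anosim_r_dry_vs_wet"] = an.r
    results["anosim_p_dry_vs_wet"] = an.p_value
    salt_abund = table.values.loc[salt_in[salt_in].index].sum(axis=0)
    sites_ser = pd.Series(table.sites)
    wt = comm.welch_t(
        salt_abund[sites_ser == "alma"], salt_abund[sites_ser == "salar_grande"]
    )
    results["saltin_abundance_alma_pct"] = float(salt_abund[sites_ser == "alma"].mean())
    results["saltin_abundance_salar_grande_pct"] = float(
        salt_abund[sites_ser == "salar_grande"].mean()
    )
    results["saltin_welch_p_alma_vs_control"] = wt.p_value
    write_table(table.values, out / "community" / "abundance_pct.tsv", prov)
    write_table(pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids),
                out / "community" / "bray_curtis.tsv", prov)
    write_table(ord_res.coordinates, out / "community" / "pcoa_coordinates.tsv", prov)

    # Trk potassium-uptake potential: salt-in taxa carry the trk system
    annotations = {
        t: set(prot.TRK_KOS) for t, flag in salt_in.items() if flag
    }
    trk = prot.trk_potential(annotations, table)
    trk_by_site = trk.groupby(sites_ser).mean()
    for site in SITES:
        results[f"{site}_trk_potential_pct"] = float(trk_by_site[site])
    write_table(trk.to_frame(), out / "community" / "trk_potential.tsv", prov)

    # ---------------- proteome ----------------
    pka = prot.PKA_SETS[config.pka_set]
    prot_dry = simulate_proteome(ProteomeSimParams(
        n_proteins=config.n_proteins, acidic_bias=config.acidic_bias_dry,
        seed=_sub_seed(config.seed, 9003),
    ))
    prot_wet = simulate_proteome(ProteomeSimParams(
        n_proteins=config.n_proteins, acidic_bias=0.0,
        seed=_sub_seed(config.seed, 9004),
    ))
    tab_dry = prot.pi_table(prot_dry, pka)
    tab_wet = prot.pi_table(prot_wet, pka)
    results["weighted_mean_pi_dry_regime"] = float(
        np.average(tab_dry["pi"], weights=tab_dry["weight"])
    )
    results["weighted_mean_pi_wet_regime"] = float(
        np.average(tab_wet["pi"], weights=tab_wet["weight"])
    )
    results["pi_welch_p_dry_vs_wet"] = comm.welch_t(tab_dry["pi"], tab_wet["pi"]).p_value
    write_table(tab_dry, out / "proteome" / "pi_dry_regime.tsv", prov, index=False)
    write_table(tab_wet, out / "proteome" / "pi_wet_regime.tsv", prov, index=False)

    # osmoadaptation profile of emblematic specialized-MAG annotation sets
    catalog = prot.load_osmo_catalog()
    mag_annotations = {
        "archaeal_saltin_A": {"trkA", "trkH", "sss", "glpK", "glpA", "glpB", "glpC",
                              "opuA", "opuC", "opuD", "opuBD", "betT"},
        "archaeal_saltin_B": {"trkA", "trkH", "sss", "glpK", "glpA", "glpB", "glpC"},
        "bacteroidetes_saltin": {"trkA", "trkH", "sss"},
        "cyanobacterium": {"glgA", "glgC", "treX", "asd", "ectB", "lysC"},
    }
    presence, complete = prot.osmo_gene_profile(mag_annotations, catalog)
    write_table(presence.astype(int), out / "proteome" / "osmo_presence.tsv", prov)
    write_table(complete.astype(int), out / "proteome" / "osmo_complete.tsv", prov)
    results["osmo_complete_strategies_archaeal_saltin_A"] = int(
        complete.loc["archaeal_saltin_A"].sum()
    )

    _figures(out / "figures", hab_frame, ord_res, table, tab_dry, tab_wet, presence)

    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {"config": cfg_dict, **prov, "results": results},
            fh, indent=2, sort_keys=True, default=str,
        )
    return results


def _figures(fig_dir, hab_frame, ord_res, table, tab_dry, tab_wet, presence) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for site, sub in hab_frame.groupby("site"):
        ax.plot(range(len(sub)), sub["wet_hours"], label=site, lw=0.8)
    ax.set_xlabel("day of record")
    ax.set_ylabel("wet hours / day")
    ax.legend(fontsize=7)
    fig.savefig(fig_dir / "daily_wet_hours.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    coords = ord_res.coordinates
    for sample in coords.index:
        site = table.sites[sample]
        ax.scatter(coords.loc[sample, "PC1"], coords.loc[sample, "PC2"],
                   label=site, s=20)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.savefig(fig_dir / "pcoa.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([tab_dry["pi"], tab_wet["pi"]], tick_labels=["dry regime", "wet regime"])
    ax.set_ylabel("predicted protein pI")
    fig.savefig(fig_dir / "pi_boxplot.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.imshow(presence.to_numpy().astype(float), aspect="auto", cmap="Reds",
              vmin=0, vmax=1)
    ax.set_yticks(range(len(presence.index)), presence.index, fontsize=7)
    ax.set_xticks(range(len(presence.columns)), presence.columns, rotation=90,
                  fontsize=6)
    fig.tight_layout()
    fig.savefig(fig_dir / "osmo_profile.svg")
    plt.close(fig)
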
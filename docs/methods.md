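# Methods

This note documents the models behind `halocline`, the defaults that
matter, and what the synthetic-data generators do and do not emulate.

## Microclimate smoothing and the 3-minute grid

Sensor loggers record temperature (°C), relative humidity (%RH), and
photosynthetically active radiation (PAR, µmol m⁻² s⁻¹) every 30 min.
To align readings across sensors, each variable is modeled per calendar
day as a smooth function of time of day and evaluated at 3-min
intervals from midnight (480 points, minutes 0, 3, …, 1437; half-open
day).

The smooth is a penalized natural cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`) with the penalty weight
chosen by generalized cross-validation.  This resolves diurnal
structure at 30-min cadence without chasing noise: on noiseless
diurnal sinusoids and ramps the 3-min grid is recovered to < 0.05
units, and error shrinks further with denser sampling (both are
tested).  Choices worth knowing:

- **Per-day, non-cyclic fits.** Days are delimited by the calendar date
  of the timestamp; no continuity is imposed across midnight.  The last
  27 min of a day (beyond the final 30-min reading) are short
  extrapolations of the day's spline.
- **Minimum data.** A day/variable with fewer than 4 usable readings is
  flagged unmodelable, skipped, and logged.  With exactly 4 readings a
  natural interpolating cubic spline is used (the GCV spline needs 5).
- **Physical clipping** is applied *after* smoothing: RH to [0, 100],
  PAR to ≥ 0; a hard post-condition checked by the `GriddedDay`
  container itself.
- **Replicate means** are pointwise arithmetic means of same-day grids;
  identical replicates average to themselves exactly.
- Daily min/max/mean can also be computed from **raw readings**
  (`env_model.raw_daily_stats`); threshold day-counts on raw vs modeled
  grids can be compared to gauge the effect of smoothing on daily
  extrema.

## Habitability windows

A 3-min grid point is *wet* when RH meets the wetting threshold and
*lit* when PAR ≥ 0.01 µmol m⁻² s⁻¹ (the minimum irradiance usable by
highly adapted primary producers).  Thresholds (`Thresholds`):

| parameter | default | meaning |
|---|---|---|
| `rh_halite_wet` | 75 %RH | equilibrium RH of saturated NaCl brine (deliquescence point) — interior positions |
| `rh_air_wet` | 95 %RH | air wetting (fog/dew collection occurs slightly below saturation) |
| `par_light` | 0.01 µmol m⁻² s⁻¹ | minimal photosynthesis |
| `strict_inequality` | False | comparisons are inclusive (≥) by default; flag switches to strict |

Each qualifying point contributes exactly 0.05 h; crossing times are
not interpolated, so daily wet hours are multiples of 0.05 in [0, 24]
and wet+light ≤ wet always.  The grid's `position` field selects the
RH threshold (air vs interior) automatically; it can be overridden.

**Wet/dry segmentation.** A day is wet iff its wet hours reach
`wet_day_min_hours` (default 1.0 h).  The day sequence is run-length
encoded and runs shorter than `min_run_days` (default 7) are absorbed
into the surrounding state, shortest first and leftmost on ties, so
single fog nights do not fragment a dry spell.  Both parameters are
configurable; the defaults were chosen once as the scale separating
brief excursions from the multi-week hydration periods of interest.
The returned periods tile the record exactly; a date gap is an error
(fill or split the record first).

## Synthetic generators

The generators provide the statistical structure the analysis assumes,
not a physical microclimate simulation.

**Air series.** Temperature is a diurnal sinusoid peaking mid-afternoon
with Gaussian noise; RH is anti-phased; PAR is a noiseless daylight
half-sine (06:00–18:00).  Fog nights occur independently with
probability `fog_prob_per_night` and lift RH toward `fog_rh_peak`
through a sharp pre-dawn bump (a sin⁶ pulse over 00:00–08:00 peaking at
04:00) — the short saturated spell of radiation fog.  Rain days force
RH ≥ 99 for the whole day.  Everything is a pure function of
(params, seed).

**Nodule interior (brine bucket).** A dimensionless reservoir in [0, 1]
recharges at `recharge_rate` per hour while air RH ≥ the deliquescence
RH and evaporates at `evaporation_rate` otherwise, clamped to [0, 1],
stepped at the sensor cadence.  While the reservoir holds brine the
interior RH sits at the deliquescence point (+ optional sensor noise);
exhausted, it relaxes exponentially toward the current air RH with
half-life `relaxation_halflife_h` (default 12 h).  Interior temperature
copies air temperature; interior PAR is 1 % of ambient at the nodule
top and 0 at middle/bottom (translucent halite transmits a small
fraction of surface light).  `interior_noise_sd` defaults to 0: the
equilibrium RH above a saturated brine is thermodynamically pinned, and
a noiseless plateau lets brine-filled records register the full 24
wet h/day that field records of brine-filled nodules show.

**Site regime presets** (`site_regime`) encode four study conditions
over a 365-day record: fog-night frequencies 85/365 (salar_grande),
239/365 (chanaral), 16/365 (yungay), 15/365 plus nine rain days in
three 3-day events around days 10/160/280 (alma).  Brine rates are set
so the coastal regimes stay brine-filled all year, the alma reservoir
drains in ~55 dry days and is refilled only by multi-day rain (three
wet periods of ~50–65 days separated by ~50–100-day dry spells), and
the yungay reservoir drains in ~120 days with no recharge (progressive
drying).  These presets target the qualitative regimes — constant-wet,
wet/dry cycling, progressive drying — not any particular sensor trace.

**Community tables.** Taxon baseline log-weights are drawn once and
shared across sites; taxa flagged salt-in (fraction `salt_in_fraction`)
gain `dryness_sensitivity × dryness_index(site)` in log-weight.
Replicates are Dirichlet draws (concentration
`dirichlet_concentration`, default 50) around the site composition,
normalized to 100 % per sample.  Defaults (40 taxa, 30 % salt-in,
4 replicates/site, sensitivity 2.0) give an effect comfortably
detectable by ANOSIM at the study's sample sizes; sensitivity 0 is the
exchangeable null.  Salt-in taxa are labeled Archaea/Euryarchaeota so
the archaea:bacteria ratio tracks the same ground truth.

**Proteomes.** Sequences are i.i.d. draws from a near-natural residue
frequency table with D/E multiplied by (1 + `acidic_bias`) and
renormalized; lengths uniform on `length_range`; uniform abundance
weights.  The generator reproduces the *direction and detectability* of
the salt-in pI shift, not absolute community pI values — real
metaproteomes are mixtures of taxa, not i.i.d. residues, so synthetic
weighted-mean pI levels should not be compared to field values.

What passing tests on these generators shows: the analysis recovers
the structure the generators encode (threshold counts, period
structure, compositional shifts, pI contrasts) at realistic sample
sizes.  What it does not show: robustness to sensor drift and gaps,
non-sinusoidal weather, compositional artifacts of real read mapping,
or pI behavior of real protein families.

## Community statistics

- **Normalization** scales each sample column to 100 %; counts are
  assumed already normalized to sample size (e.g. per-million-reads) —
  the step is idempotent and rejects all-zero samples by name.
- **Archaea:bacteria ratio** = Σ archaeal / Σ bacterial abundance per
  sample; site value is the mean over samples.  Features without a
  domain label are excluded from both sums and counted in the log; a
  zero-bacteria sample yields +inf with a warning.
- **MAG rules.** Quality filter keeps completeness ≥ 70 % and
  contamination ≤ 5 % (inclusive).  Species dereplication builds
  single-linkage clusters over pairs with ANI ≥ 95 % *and* aligned
  coverage ≥ 10 % (inclusive; missing pairs are below threshold);
  the representative maximizes completeness − 5·contamination, ties
  broken by id.  Linkage and score are documented choices, pluggable
  by passing different thresholds.  Specialized MAGs are those whose
  per-site mean abundance exceeds 10 % (strictly) in at least one site.
- **Bray–Curtis** via `scipy.spatial.distance.pdist`; distances live in
  a `skbio DistanceMatrix`.
- **PCoA** is classical scaling: double-center −D²/2, eigendecompose,
  keep positive-eigenvalue axes; negative eigenvalues (non-Euclidean
  input) are reported as diagnostics, and variance explained is taken
  over positive eigenvalues.  On Euclidean input the embedding
  reproduces pairwise distances to 1e-8 (tested).
- **ANOSIM** ranks the upper-triangle distances with midranks for ties;
  R = (r̄_between − r̄_within)/(n(n−1)/4), confined to [−1, 1].  The
  p-value uses the add-one convention
  p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm) over random relabelings;
  `exact=True` enumerates all n! relabelings (n ≤ 9).
- **Welch's t** is two-sided via `scipy.stats.ttest_ind(equal_var=False)`
  with Welch–Satterthwaite df.  Two zero-variance groups with equal
  means return t = 0, p = 1; with unequal means they are an error.  No
  multiple-testing correction is applied by default (per-comparison
  p-values are reported raw); Benjamini–Hochberg can be layered on via
  `statsmodels` if many comparisons are run.

## Isoelectric points and osmoadaptation profiles

Net charge at a given pH follows the Henderson–Hasselbalch model over
side chains D, E, C, Y (acidic), H, K, R (basic), and both termini:

  Z(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH)).

Ambiguous residues (B, Z, X, U, O) are charge-neutral and logged.  The
pKa constants default to the EMBOSS set (D 3.9, E 4.1, C 8.5, Y 10.1,
H 6.5, K 10.8, R 12.5; N-term 8.6, C-term 3.6); alternative sets can be
registered.  Different pI tools use different constants, so absolute pI
values can differ by ~0.1–0.3 units between tools; comparisons should
hold the pKa set fixed.

The pI is the unique zero of the strictly decreasing Z(pH), found by
bisection on [0, 14] driven to a bracket of 1e-6 pH — accurate in pH
units even where the charge curve is nearly flat, and matching a 1e-4
fine-grid scan oracle to < 2e-4 (tested on 1000 random sequences).  The
community-weighted mean pI weights each protein by its source contig's
relative abundance (equal-weight mode available); protein-length
weighting is a plausible alternative not implemented by default.

Trk potassium-uptake potential is the per-sample summed relative
abundance of features annotated with K03498 (trkH) or K03499 (trkA); a
feature carrying both counts once.  The osmoadaptation catalog
(`data/osmo_genes.yaml`, editable) maps strategies — potassium uptake,
sodium:solute symport, compatible-solute uptake (opuA/opuC/opuD/
opuBD/betT), glycerol utilization (glpK + glpA/glpB/glpC), trehalose
biosynthesis (glgA/glgC/treX), ectoine biosynthesis (asd/ectB/lysC) —
to gene symbols with KO aliases; a strategy is "complete" for a MAG
when every gene is present.  No KO may appear in two strategies.

## Numerical and reporting choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of (params, seed), and pipeline stages
  derive sub-seeds deterministically from the run seed.
- Output tables carry a `#`-prefixed provenance header (config hash,
  seed); reruns with the same config and seed are byte-identical.
- The end-to-end report (`halocline report`, `scripts/acceptance.py`)
  uses a 365-day record, 3 replicate nodule sensors per site, 40 taxa ×
  4 replicate samples per site, 200 proteins per regime, and 999 ANOSIM
  permutations — sizes chosen so a full run completes in a few minutes
  on one core while keeping every statistic at the study's scale.

## Known limitations

- The brine bucket is a two-state caricature: no brine chemistry, no
  hysteresis between deliquescence and efflorescence, no thermal
  coupling of reservoir dynamics.
- Per-day spline fits can ring near day boundaries on sparse or very
  noisy days; extrema taken from modeled grids may slightly exceed raw
  extrema.
- Period segmentation is threshold-plus-merging, not a changepoint
  model; records dominated by days hovering at the wet-day threshold
  will be sensitive to `wet_day_min_hours`.
- ANOSIM exact enumeration is factorial and capped at n ≤ 9 samples.
- Taxonomy, KO annotations, ANI/coverage, and MAG quality are inputs;
  the package neither bins, classifies, nor annotates sequence data.
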
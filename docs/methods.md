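# Methods

## The degree-day voltinism model

Insect development above a lower thermal threshold is, to first order,
proportional to accumulated heat.  For daily mean temperatures
`T_i` over one calendar year, the cumulative growing degree days are

    CGDD = sum_i max(T_i - T0, 0)

with developmental zero `T0`, and voltinism is the continuous ratio
`N = CGDD / K`, where `K` is the degree-day requirement for one complete
generation (egg → adult).  Three modelling commitments follow:

* **No upper developmental threshold and no diapause/photoperiod
  switch.**  The linear model accumulates heat without saturation; this
  is a known limitation at the warm end (real development plateaus and
  diapause can cap the realized number of generations), and it is
  intentional: the package implements the plain linear model, and its
  projections should be read as thermal potential, not realized
  phenology.
* **N is continuous.**  1.4 generations is a meaningful state (the
  second generation is 40 % provisioned); flooring would discard the
  quantity the gradient and trend analyses operate on.
* **Leap days count.**  On the Gregorian calendar day 366 enters the
  sum; the default synthetic calendar is 365-day ("noleap"), which keeps
  the analytic test anchors exact.

Default parameters for the pine caterpillar ship as
`src/voltigrid/data/developmental_parameters.csv`: whole-generation
`T0 = 9.95 ± 0.61 °C`, `K = 1698.18 ± 48.18` degree-days, with the four
life-stage rows (larvae after overwintering, pupae, egg, larvae before
overwintering).  `stage_table_consistency` verifies that the stage K
values sum to the whole-generation K within 0.02 degree-days (they sum
to 1698.19, a 0.01 rounding residue).  The `±` values are standard
errors from the underlying rearing experiments; `parameter_uncertainty_band`
propagates them by recomputing the degree-day sum with `T0 ± SE` and
dividing by `K ± SE` (slow bound: `T0+SE`, `K+SE`; fast bound: `T0-SE`,
`K-SE`).  Period summaries quoted as `mean ± value` are the mean ± SD of
annual domain-mean voltinism across the years of the period.

## Synthetic climate generator

The generator emulates the two inputs the analysis consumes — an
observed 0.1°-style baseline and 0.25°-style scenario ensemble members —
without reproducing any real geography.  Daily temperature at a cell is

    T(cell, year, doy) = A(cell) + W(year) + I(year) + S(doy) + e(doy)

with:

* **Annual-mean field** `A = T_ref + g·(lat − lat_min) + Γ·elev/1000`.
  Defaults: `T_ref = 15.0 °C` at the southern edge at sea level,
  meridional gradient `g = −0.55 °C/°lat`, lapse rate `Γ = −6.5 °C/km`.
  Together with the default DEM these put the domain-mean annual
  temperature near 12.5 °C, inside the 11.2–14.4 °C band of a warm
  temperate province, which the tests check on simulated years.
* **Baseline warming** `W(year)` linear at 0.3 °C/decade, anchored at
  the midpoint of the baseline period (so the configured reference mean
  *is* the baseline-period mean).
* **Interannual effect** `I(year)`: i.i.d. N(0, 0.35 °C), shared across
  the domain within a year.
* **Seasonal cycle** `S(doy) = −A_s·cos(2π(doy−15)/n_days)` with
  amplitude `A_s = 14 °C` and minimum on day-of-year 15 (mid-January).
  On integer days the minimum phase is attained exactly (day 15), while
  the maximum phase falls between days 197 and 198, so the discrete
  maximum sits `O((π/365)²)` below `A_s` — the mean-to-minimum distance
  is the exact amplitude anchor the tests use.
* **Weather noise** `e`: AR(1) with SD 2.0 °C and lag-1 autocorrelation
  0.7, initialized from its stationary distribution at each year
  boundary (the chain restarts yearly; the induced bias in the sample
  autocorrelation is < 0.01 for multi-decade series).

The synthetic DEM is a deterministic Gaussian massif (peak ≈ 1300 m)
over a 60 m coastal plain plus seeded roughness, clipped at 0 m; at the
default domain it populates all three elevation bands.

**Scenario ramps.**  Each scenario is defined by its end-of-century
warming over the baseline mean (defaults 2.37 / 3.45 / 4.35 / 5.49 °C
for SSP1-2.6 / 2-4.5 / 3-7.0 / 5-8.5).  The ramp is linear from 2015,
starts at the extrapolated baseline trend (so the historical-to-scenario
transition is continuous), and its slope is solved so that the
2081–2100 mean anomaly relative to the baseline-period mean equals the
configured warming *exactly* — a property the tests verify per cell at
zero noise and in 95 %-CI terms under default noise.  Warming is
spatially uniform by default.

**Pseudo-GCM members** add a constant bias, a multiplicative inflation
of the seasonal amplitude, and independent daily noise.  All noise
streams are seeded per `(seed, year)` (plus a member offset), so a
member with zero bias/noise and unit inflation reproduces the observed
generator bit-for-bit on shared years, and output never depends on which
year range was requested.  The default ensemble has 5 members of
graded quality, enough to exercise selection at desk scale.

**What the generator does not emulate:** spatial warming patterns,
precipitation/humidity, temperature extremes beyond AR(1) + sinusoid,
real coastlines or orography, and GCM-specific error structure.  Passing
tests therefore demonstrate the *pipeline's* correctness and the
model's analytic properties, not fidelity to any real region's climate.

## Ensemble evaluation

Members are compared with the baseline on the **domain-mean daily
temperature series** over the period overlap, after aligning calendars
on (year, day-of-year).  The Taylor triple uses population (1/n)
moments, so the centered-RMSE law
`cRMSE² = σ_sim² + σ_obs² − 2σ_sim σ_obs r` holds to machine precision;
normalized SD and normalized cRMSE (÷ σ_obs) are reported alongside the
raw values because published evaluation numbers are often on the
dimensionless Taylor scale.  Ranking uses the standard Taylor skill
score

    S = (1 + r)^4 / (4 (σ̂ + 1/σ̂)²),   σ̂ = σ_sim/σ_obs,

which lies in (0, 1] and is 1 iff r = 1 and σ̂ = 1.  Ties break
alphabetically.  Equal weighting is the default for the multi-model
mean; `skill-weighted` sets `w_i ∝ S_i`.

## Regridding and extraction

All inputs are interpolated **bilinearly** to the common analysis grid
(default 0.05°; the test profile uses 0.5°).  Bilinear interpolation is
exact on fields linear in lat/lon, never leaves the source min/max
envelope, and is idempotent at a fixed resolution — all three are
tested.  No extrapolation: target centers outside the source hull are
masked.  Elevation is regridded the same way.  Point extraction takes
the nearest cell center by great-circle distance, with exact ties going
to the south-west cell for determinism.

## Gradients, trends and regressions

* **Bins.**  Elevation: `[0, 500)`, `[500, 1000]`, `(1000, ∞)` m
  (1000.0 m belongs to the middle band).  Latitude: left-open
  right-closed intervals (34.5–35], (35–36], (36–37], (37–38],
  (38–38.5] °N; a cell at exactly the open southern edge is masked.
  Bin means are **unweighted** over cells: across a 4° band the
  cos-latitude area distortion is ≲ 0.5 %, and unweighted means keep the
  hand oracles exact.
* **Decadal trends.**  OLS of the annual value on calendar year, slope
  and 95 % t-based CI reported ×10 ("per decade").  A constant series
  returns slope 0 with R² = 0 by convention (the R² of a zero-variance
  response is undefined; 0 is the conservative report).
* **ΔN-vs-ΔT regressions.**  For one bin × scenario, annual bin-mean
  voltinism and annual-mean temperature anomalies (both relative to the
  baseline-period bin mean) are pooled across projection years
  (2019–2100 → 82 points) and fit by OLS.  The fit reports generations
  per °C, R², and predicted ΔN at +1, +1.5 and +2 °C.

A useful closed form bounds these slopes: shifting an
all-above-threshold 365-day year uniformly by ΔT changes CGDD by exactly
365·ΔT and N by (365/K)·ΔT ≈ 0.215·ΔT.  Realized slopes on seasonal
data are strictly smaller (winter days sit below the threshold and
absorb part of the warming before it accrues); the default synthetic
pipeline realizes ≈ 0.14 generations/°C, inside the (0, 365/K) interval.

## Pipeline and determinism

`run_pipeline` executes synth → evaluate → ensemble (per scenario) →
regrid → CGDD/voltinism → gradients → report, writing NetCDF (via the
scipy backend, classic format) and CSV artifacts plus a JSON manifest
with the full config, stage timings and SHA-256 checksums of every
artifact.  Identical config + seed reproduces identical checksums.  The
seed is mandatory everywhere — no silent default.  Exit codes: 0 ok,
2 config error, 3 data error.

Problem sizes: the shipped test profile runs the full pipeline at 0.5°
resolution with a 15-year baseline, 3 members and 2-scenario/short
future windows; analytic and oracle tests use single cells or ≤ 5×5
grids.  These sizes were chosen so the whole suite exercises every
stage in well under a minute of compute while leaving the statistical
checks (AR(1) recovery, CI coverage over 20 seeds) adequately powered.

## Known limitations

* Linear degree-day accumulation without upper threshold or diapause
  overestimates voltinism under strong warming.
* The ΔN-vs-ΔT pooling treats projection years as independent points;
  serial correlation inflates R² relative to an effective-sample-size
  analysis (no correction is applied, matching standard practice in
  gradient summaries).
* Unweighted bin means are only appropriate for narrow latitudinal
  extents.
* The synthetic generator's spatially uniform warming cannot produce
  regionally differentiated change patterns; conclusions about spatial
  heterogeneity require real forcing fields.
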
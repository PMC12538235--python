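# Methods

## Scope and data flow

The pipeline maps per-case exposure fields to attributable health burden:

1. **Exposure preparation** — annual-mean PM2.5 per case, optionally
   downscaled against a fine satellite reference; annual-mean MDA8 O3,
   computed from hourly series where available; a zero-anthropogenic
   (OFF) companion field per case.
2. **Hazard ratios** — GEMM for PM2.5/NCD+LRI per adult 5-year age group;
   a log-linear threshold model for O3/COPD.
3. **Burden** — attributable deaths M = POP × BMR × (HR−1)/HR and
   YLL = M × MYLL per cell, endpoint and age; CI members low/central/high.
4. **Aggregation** — cell-exhaustive regional sums over an 11-region
   mask, per-100,000 rates, pooled developed/developing comparison,
   cross-case percent differences.
5. **Validation** — station matching, NMB, Pearson r, gridded mean bias
   on a coarse comparison grid.

Net-anthropogenic burden is the difference of case and OFF **totals** per
CI member, computed after summation, never clamped at zero.

## Grids and regridding

Grids are regular, cell-centered, latitude ascending, longitude in
[−180, 180), with half-open midpoint-to-midpoint cell bounds (clipped at
the poles). Grid spacing is data, not a constant — the same code serves
~1° model grids, the 0.1° analysis grid and the 2° comparison grid.

Intensive fields (concentrations, fluxes) are regridded bilinearly
(nearest-neighbour available); extensive fields (population, emission
mass, deaths) must use the conservative overlap-area-weighted remap, which
preserves their global integral to machine precision because each source
cell's stock is split among targets in proportion to fractional overlap
(latitude overlaps evaluated in sin φ so fractions are true spherical
areas; longitudes compared at shifts of ±360° to handle antimeridian
wrapping). The Earth is a sphere of radius 6.371×10⁶ m. Bilinear/nearest
interpolation delegates to `scipy.interpolate.RegularGridInterpolator`
with target coordinates clamped to the source range (edge cells take edge
values, never extrapolations); the conservative kernel is written here
because no installed library provides one.

## Exposure conventions

* **MDA8**: per day the maximum over running 8-hour means. Default
  convention is *same-day* (17 windows, start hours 0–16), chosen for
  self-containment: it never needs the next day's data. The *epa*
  convention (24 start hours, the last seven crossing midnight) is
  selectable. A day needs ≥ 18 of 24 valid hours (75%); a window needs
  ≥ 6 of its 8 hours; the annual mean runs over valid days only.
* **Downscaling** is multiplicative: the coarse model is interpolated
  bilinearly to the satellite grid and multiplied by the clipped ratio
  satellite/model, factors limited to [0.1, 10]. Multiplication (rather
  than additive or regression adjustment) preserves non-negativity and
  makes the scheme exact-recovering: if the satellite field is itself a
  bilinear upsampling of the model, the output is the satellite field.
  Where the reference is missing the factor is 1. Alternative estimators
  can be plugged in by constructing a `CalibrationMap` directly.

## Hazard models and uncertainty

GEMM's logistic weight ω(z) multiplies θ·ln(1+z/α) *inside* the
exponential; HR is exactly 1 at and below the 2.4 μg/m³ counterfactual,
and monotone in both concentration and θ (θ, ν > 0), which guarantees
low ≤ central ≤ high after every downstream aggregation. The O3 model's
exposure metric is annual-mean MDA8 with ΔY = max(0, Y − 26.7 ppb) and
η = 0.0131 (95% CI 0.0077–0.0191) for COPD; the stricter COPD slope is
used rather than an all-respiratory alternative.

Both models are applied to adult age groups (25–29 … 80+). CI propagation
perturbs only θ (at ∓1.96·SE) or η (at its published bounds); population
and BMR are treated as fixed. Combined PM2.5+O3 totals add the two
pollutants' bounds member-wise — a deliberately simple convention that
reproduces combined-row arithmetic in published summary tables; it is
conservative relative to quadrature combination.

GEMM fit values are not hard-coded: they load from a CSV with schema
`endpoint,age,theta,se_theta,alpha,mu,nu`. The bundled
`GEMMParams.synthetic_default()` table is synthetic — GEMM-shaped (θ
declining with age over a common α, μ, ν) and intended for tests and
demos, not for quantitative reuse.

Burden arithmetic notes: exposure values are floored at zero before HR
evaluation (net difference fields can dip negative); the attributable
fraction (HR−1)/HR is strictly < 1 so M can never exceed the stratum's
total deaths POP × BMR.

## Aggregation conventions

Regional sums are cell-exhaustive partitions: any refinement of the mask
leaves the global total unchanged, and unlabelled cells go to an explicit
"unassigned" row rather than being dropped. The developed group is USA,
Canada, WEUROPE and ROW; all other regions are developing. Group rates
are pooled (Σ deaths / Σ population), not averages of member-region rates.
Reporting rounding (totals to 0.1 thousand, rates and shares to 1 decimal,
comparison percentages to integers) is applied after all arithmetic, on
unrounded intermediates.

## Validation statistics

Stations are matched to the containing grid cell under the half-open
bound convention (a station exactly on an interior edge belongs to the
upper cell, deterministically); stations outside the grid are dropped
with a logged count. Multiple stations in one cell each form their own
pair by default (`average_per_cell=True` switches to pre-averaging).
NMB = Σ(model−obs)/Σ(obs) × 100. Pearson r delegates to
`scipy.stats.pearsonr`. The gridded mean bias regrids the model
bilinearly to the observation grid, differences only where observations
exist, and averages unweighted over valid cells (area weighting behind a
flag), leaving unobserved cells missing. Annual station means are assumed
throughout; no matched-month screening is attempted.

## Synthetic world

The generator suite emulates the statistical structure of the real
inputs, not their geography:

* **Concentrations**: lognormal background exp(N(ln median, σ²)) — default
  median 10 μg/m³, σ_log 0.5 for PM2.5; 35 ppbv background with 20 ppbv
  plumes for O3 — plus Gaussian hotspot plumes (default 8 hotspots,
  amplitude 30, e-folding radius 12°) centred uniformly on the sphere
  (cos-lat weighted).
* **Case/OFF pairs**: OFF = case × (1 − anthropogenic share); demo shares
  0.50/0.55/0.40 for the three cases, spanning the plausible range of the
  anthropogenic contribution.
* **Population**: 7.3 billion (mid-2015 world total), 54% of the mass in
  urban Gaussian clusters, the rest uniform per unit area, total exact by
  normalization. Age pyramid: geometric decay, ratio 0.93 per 5-year
  group — a plausible world pyramid, overridable.
* **BMR/MYLL**: rates rising ×1.45 per 5-year group from 2×10⁻³
  (NCD+LRI) / 2×10⁻⁴ (COPD) at 25–29, capped at 0.5; MYLL = 86 − age
  midpoint, floored at 5 years; ±30% seeded regional multipliers.
* **Stations**: cell-truth × (1+ε), ε ~ N(0, cv²) truncated at −0.9;
  default 100 stations, cv 0.1.
* **Inventories**: lognormal spatial patterns normalized so each species'
  area-integral equals its prescribed Tg/yr exactly.
* **Region mask**: an 11-label tiling (longitude bands × latitude blocks,
  seed-shuffled) — synthetic tiles, not country borders; exhaustive so
  partition identities hold exactly.

What passing tests on this world do **not** show: realistic spatial
covariance between population and pollution (real burdens concentrate far
more sharply), real country borders or region assignment, chemistry-driven
case differences (cases differ here only through seeds and shares), or
calibration of absolute burden magnitudes. The tests establish the
arithmetic, conservation, monotonicity and inversion properties of the
machinery; absolute numbers from the demo are properties of the synthetic
world.

## Determinism and the pipeline driver

One integer seed drives everything through spawned, per-generator RNG
streams (`SeedSequence(seed, spawn_key=stream)`); per-case streams derive
as seed×1000+offset. The driver validates its YAML config strictly
(unknown keys refuse — a typo must not silently change burden
attribution), stamps every CSV with a hash of the scientific config
(output paths excluded) and the package version, and logs cell counts,
global integrals and dropped-record counts at stage boundaries. Reruns
with the same config and seed are byte-identical. Demo problem sizes
(36×72 global grid, 100 stations) keep the full pipeline under a few
seconds while exercising every stage; all operations are resolution-
agnostic and run unchanged on 0.1° fields.

## Known limitations

* NetCDF I/O uses the classic format (xarray/scipy backend); NetCDF4/HDF5
  files must be converted before ingestion.
* No morbidity endpoints, no IER curves, no cause-decomposed NCD
  sub-causes, no life-table age shifting beyond the MYLL product.
* The CI-addition convention for combined pollutants overstates combined
  uncertainty relative to independent-error quadrature.
* Bilinear regridding of concentrations is not conservative; it is the
  deliberate choice for intensive fields, with conservation reserved for
  stocks.
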
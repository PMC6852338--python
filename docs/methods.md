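# Methods

This note records the scientific and numerical choices behind each module:
what is modelled, the defaults and their units, what the synthetic
generators do and do not emulate, and the decisions taken where the design
was genuinely open.

## Emission model

The core is the temperature-exponential Guenther formulation. Per cell and
hour, `E = EF · M(T) · FBD · A` with `M(T) = exp(β(T − T_s))`. Constants:
β = 0.09 K⁻¹ and T_s = 303 K (configurable through
`EmissionModelConstants` for sensitivity work, but these are the model's
standard values); cell area defaults to 900 m², i.e. a 30 m pixel, and is
taken from the land-cover grid when an inventory is run. Leaf temperature
is taken equal to air temperature. Only the temperature response is
modelled; there is no light-dependent (PAR) term, canopy radiative
transfer, or downstream chemistry — monoterpenes and "other BVOC" differ
only in their emission factors.

Aggregation is definitional, not calendrical: daily = Σ of 24 hourly
values, monthly = 30 × daily regardless of true month length, annual = Σ of
12 monthly values. The inventory uses one representative diurnal cycle per
month (24 hourly temperature surfaces), so the summation order is fixed as
hours → day → ×30 → months; cells of a species are summed at month level.
Totals convert at 1 metric ton = 10¹² µg. Emission is therefore exactly
linear in EF, FBD and area, and strictly increasing in any cell's
temperature — both properties are tested.

The bundled parameter table (`synthetic_default_params`) is synthetic: the
values are plausible literature-scale magnitudes chosen so examples and
tests run self-contained (high monoterpene factors for eucalypt and pine,
a near-zero one for alder). Real inventories must load their own table via
`read_params_csv`.

## Land cover

Classification is per-pixel Gaussian maximum likelihood on the raw band
vector (red, NIR): class means and covariances estimated from
training-polygon pixels, discriminant
`ln π_k − ½ln|Σ_k| − ½(x−µ_k)ᵀΣ_k⁻¹(x−µ_k)`, ties resolved to the lowest
class id so results are deterministic. Priors default to equal (a
proportional-to-training-size option exists). Covariances are regularised
by adding `10⁻⁶ × mean(diag Σ)` to the diagonal, which keeps degenerate
(constant) training sets classifiable; the factor is a parameter. NDVI can
be appended as a third feature by callers, but the default feature space
is the two bands — NDVI's role is the separability argument, not the
classification itself.

Accuracy assessment uses the standard confusion matrix with overall
accuracy (trace/total) and Cohen's kappa from the row/column marginals;
0.85 kappa is the conventional "almost perfect" threshold the tests hold
the synthetic recovery to. Areas are pixel counts × pixel area (1 ha =
10⁴ m²). Two-date change reports Δha and the signed annual rate
Δha/years, with losses labelled deforestation and gains increase; the
two study dates being three years apart, rates in the tests use
years_between = 3. `change_from_areas` exposes the same arithmetic for
externally tabulated areas.

## Spectra

Detector-junction steps are corrected additively: at each junction the
segment beyond it is shifted so the first value after equals the last
value before, junctions processed left to right so shifts cascade; output
clipped to [0, 1]. Additive (not multiplicative) correction is the choice
consistent with a level offset between detectors, and makes the operation
idempotent. Default junctions are 1000 and 1800 nm, typical of
three-detector field spectroradiometers.

Out-of-trend spectra are rejected in a single pass when the mean absolute
deviation of a spectrum from the per-wavelength group **median** exceeds
`k` (default 3) times a robust grid-average spread (1.4826 × per-wavelength
median absolute deviation). A robust centre/scale is used rather than the
group mean and pooled standard deviation because planted outliers inflate
the non-robust statistics enough to mask themselves at realistic outlier
fractions (10–20%); with the robust form, recovery of planted outliers
separated by ≥ 5 noise standard deviations is exact in simulation. If the
spread is exactly zero (identical members up to exact departures), any
nonzero deviation is rejected; `k = ∞` disables rejection.

Representative signatures are per-wavelength arithmetic means of the kept
members. Field NDVI averages reflectance over 640–670 nm (red) and
850–880 nm (NIR), both windows inclusive — 31 samples each on a 1 nm grid
— and returns (NIR−R)/(NIR+R). Reflectance is canonicalised to fractions;
the CSV reader accepts percent input with `unit="percent"`. Vegetative
states are canonicalised to sapling/timber (synonyms "small trees"/"high
trees" accepted).

## Temperature fields

Stage 1 converts daily summaries to hourly values: per station and per
hour-of-day, OLS of the hour-h temperature against the day's mean
temperature, taken as (daily min + daily max)/2. Which pairing the "ax+b"
regression uses was an open design point; regressing the hour-slot
temperature on the daily mean is the minimal scheme that turns daily data
into hourly maps, and an externally supplied daily summary is accepted for
calibration studies. Hour slots with fewer than 3 observations borrow the
circularly nearest populated slot's coefficients and are flagged in
`filled_hours_`; a constant (zero-variance) regressor yields slope 0 and
intercept at the observed mean.

Stage 2 is universal kriging. The semivariogram defaults to spherical,
fitted by weighted least squares (weights √pair-count) to the empirical
variogram of drift-detrended residuals; exponential, Gaussian and linear
models are available, and a `VariogramSpec` can be supplied directly. The
drift is linear in x and y by default (constant-only available); an
altitude drift term is deliberately not included by default. The nugget is
forced to 0 by default, making the predictor an exact interpolator at the
stations; the constant drift term enforces weights summing to 1, so a
constant added to all station values passes straight through, and any
field lying in the drift space (e.g. a plane under linear drift) is
reproduced exactly regardless of the variogram. When the residual process
is degenerate (field exactly in the drift space) a well-conditioned linear
variogram is substituted, since the fitted one would make the kriging
system singular without changing the prediction. Systems with condition
number above 10¹⁴, duplicate station coordinates, or fewer than 4 stations
are rejected with diagnostics.

Temperatures are °C throughout and convert to K only inside the emission
model.

## Statistics

- Finite-population sample size `n = Z²pqN/(NE² + Z²pq)`; the integer
  size is the ceiling of the raw value capped at N (one cannot sample more
  than the population). Defaults Z = 1.96, p = q = 0.5, E = 0.05.
- Pearson correlation via the product-moment formula with a two-sided
  t-test on n−2 df; default confidence level 99% (α = 0.01). r and r² are
  reported separately.
- Moving average of order 3 (configurable) is centred with no edge
  padding, so output shrinks by order−1 — it is a plotting smoother, not a
  forecaster.
- Two-way ANOVA is the classical fixed-effects decomposition with
  sequential sums of squares, valid because only balanced designs are
  accepted; unbalanced inputs and empty cells are rejected explicitly
  rather than silently reweighted. The interaction term is included when
  every cell has ≥ 2 observations. Tukey HSD runs on each factor's level
  means at α = 0.05. The all-equal input degenerates to SS_total = 0 and
  undefined F, reported as such.

## Synthetic data

Each generator draws from its own stream, `default_rng([tag, seed])` with
a fixed distinct tag per generator, so outputs are bit-reproducible and
the generators are mutually independent at equal seeds.

- **Scenes**: labelled polygonal patches (default: equal vertical strips)
  covering a 30 m grid; band values Gaussian around per-class means,
  clipped to [0, 1] (clipping bias is negligible at the default means and
  std). Default classes model three forest species with class-mean
  separations of ≥ 4 band standard deviations (std 0.02) — spectrally
  distinct, as plantation species are against each other, but not
  noise-free. Training polygons are the patches shrunk by half towards
  their centroids, mimicking conservative field training areas. Not
  emulated: atmospheric effects, clouds/shadows, mixed pixels,
  within-class spatial autocorrelation — so a high synthetic kappa shows
  the estimator chain is correct, not that real scenes of these species
  would classify this well.
- **Stations**: T = base + seasonal cosine + diurnal cosine (peak at
  14:00, within the early-afternoon maximum of real records) − lapse ×
  (altitude − reference) + Gaussian noise. Defaults: 7 stations between
  2700 and 3600 m, base 13 °C at 3000 m, lapse 0.0065 °C m⁻¹, diurnal
  amplitude 5 °C, seasonal amplitude 1 °C (equatorial Andes have weak
  seasonality), noise 0.5 °C. Not emulated: weather fronts, inversions,
  missing data runs.
- **Signatures**: archetype + noise, with additive steps at the detector
  junctions and a configurable fraction of planted outliers (offset by a
  multiple of the noise std), flagged in the returned ground truth.
- **VOC/meteorology**: VOC is a linear response to independent Gaussian
  temperature, radiation and wind drivers (signs +, +, −) plus noise;
  `population_correlations()` returns the closed-form corr(VOC, driver),
  which the correlation-recovery tests compare against. Observation times
  fall in the 11:00–15:00 window.

## Problem sizes and determinism

Test and demonstration runs use scenes from 24×24 to 200×200 pixels,
30–60-day station records and 500-observation correlation samples — sizes
at which every statistical check has comfortable power while the full
suite stays quick. The pipeline runner derives all randomness from one
seed recorded in the manifest, and identical config + seed reproduces
byte-identical tables; product hashes in the manifest make this checkable.

## Known limitations

- The inventory treats each cell as 100% covered by its mapped class; no
  sub-pixel cover fractions.
- Month length is fixed at 30 days by the aggregation scheme, so annual
  totals assume a 360-hour-day-structured year (this is the model's
  definition, not an approximation error).
- Kriging variance is available but only as a diagnostic; no co-kriging,
  no altitude drift by default.
- The ANOVA path supports balanced designs only.
- Real-data reproduction of published area and emission totals requires
  the corresponding external tables (emission factors, biomass densities,
  station records, scenes); the package validates the machinery on
  synthetic ground truth instead.
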
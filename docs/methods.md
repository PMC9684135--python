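# Methods

`firethresh` implements a fire-climate risk analysis built around a single
statistical object: a binomial-logit model of daily forest-fire occurrence as
a function of daily-maximum vapour pressure deficit (VPD), from which a
critical fire-activity threshold is extracted and projected forward under
bias-corrected model climate. This note records the model, the conventions,
the synthetic world the tests run against, and the design choices that were
genuinely open.

## The occurrence model and the VPD threshold

For each stratum (a forest-biome × sub-continental-window combination) the
probability that a grid cell is recorded as burnt on a given day is modelled
as

    P(fire | VPD = v) = logit⁻¹(β₀ + β₁ v)

fitted by maximum likelihood (IRLS via `statsmodels` GLM, binomial family,
logit link, deviance tolerance 1e-8, max 100 iterations). The quantity of
interest is the **fire-activity threshold**

    VPD_P50 = −β₀ / β₁      [kPa]

the VPD at which the fitted probability of fire crosses 50%. It is defined
only for β₁ > 0; a non-increasing response raises an explicit error rather
than returning a meaningless ratio.

The standard error of VPD_P50 uses first-order (delta-method) propagation of
the coefficient covariance Σ: with g = (−1/β₁, β₀/β₁²),
SE² = gᵀΣg, and the reported confidence interval is VPD_P50 ± 2·SE. The
delta method is exact only asymptotically; the test suite cross-checks it
against a 500-replicate nonparametric bootstrap (agreement within 10% at
n = 2000).

Skill diagnostics per stratum:

* **AUC** — trapezoidal integration of the ROC over unique score values;
  score ties contribute half weight, so the statistic equals the
  Mann–Whitney pair fraction exactly (the tests verify this against an
  O(n²) enumeration to 1e-12).
* **TPR** — fraction of fire rows with predicted probability ≥ 0.5. Ties at
  exactly 0.5 count as positive predictions; with a single monotone
  predictor this is identical to classifying by VPD against VPD_P50.
* **Deviance explained** — 1 − residual/null deviance (intercept-only null),
  reported as a percent.

**Perfect separation** (all fire VPDs above all non-fire VPDs) is detected
before fitting; the threshold is then the midpoint of the separating gap,
the slope is flagged infinite, and no covariance is reported. An all-one-
label stratum is reported unfittable, never silently dropped.

## Presence / quasi-absence sampling

Presences are the daily VPD at the same day and great-circle-nearest climate
cell to each burned-area record; several fine fire cells inside one coarse
climate cell legitimately share a VPD value. Geometric near-ties (within
1e-6 km) resolve to the lowest (lat, lon) index so matching is deterministic.

Quasi-absences are (cell, date) pairs drawn uniformly **without replacement**
from the eligible pool of each stratum-year: cells inside the stratum mask,
unburned on the drawn date, and with no burn in the half-open window
[date − 5 years, date). The window is closed at its lower edge: a burn
exactly five 365-day years before the date still excludes the cell. Each
year receives exactly as many absences as presences, so label balance holds
per year and overall by construction; an exhausted pool is a hard error
naming the year and stratum. Dates are uniform over the whole year, not
weighted by fire season. Without pre-period burn records the first years of
a study are left-censored with respect to the filter; this is logged.

Because the design is balanced case-control, the fitted intercept absorbs
the sampling odds and VPD_P50 sits where the fire-day and non-fire-day VPD
distributions cross — the same convention as the threshold maps this package
emulates. Recovery benchmarks therefore generate validation samples
*directly* from a planted law at VPD values centred on the planted
threshold, where labels are naturally near-balanced and the MLE is an
unbiased estimate of the planted coefficients.

## VPD thermodynamics

Daily VPD is computed **at the time of the daily maximum air temperature**:
for each cell-day the sub-daily step with the highest temperature is located
(ties → earliest step) and VPD is evaluated from the temperature and
humidity at that step. This is deliberately *not* the daily maximum of
pointwise VPD — a cool very-dry hour must not win — and one test constructs
exactly that situation.

Saturation vapour pressure uses the Magnus–Tetens curve over liquid water,
e_s(t) = 0.6108·exp(17.27 t/(t + 237.3)) kPa (t in °C), a standard choice in
fuel-moisture work; it is isolated in one function so an alternative curve
can be swapped in. Humidity may be dew point (VPD = e_s(T) − e_s(T_d),
rejecting supersaturation) or relative humidity (VPD = e_s(T)(1 − RH/100)).
RH in (100, 100.5]% — rounding artefacts — is clamped to saturation with a
logged count; anything larger is rejected. Day boundaries are taken in the
grid's native time zone; no solar-time correction is applied.

## Bias correction and the delta convention

Model VPD is corrected by empirical quantile mapping against a reference
(reanalysis-like) daily series: 99 percentiles by default, piecewise-linear
interpolation between the (source, target) quantile pairs, additive offset
beyond the outermost quantiles, output clamped at 0 kPa, fitted per calendar
month by default (an all-year switch exists and both paths are tested). A
constant source series cannot define a spread correction and falls back to a
flagged identity-with-offset map.

Projected change is always **modelled future minus modelled present**, both
passed through the same correction — the observed climatology never enters a
difference, so constant model bias cancels. The delta is taken on the
derived exceedance-day statistic, matching how change maps are built
downstream, not on the VPD values themselves.

In the synthetic world the model's bias is a fixed affine distortion
(scale, then shift) applied to whatever the model simulates, and the planted
warming delta lives in reference space: future = scale·(base + δ) + shift.
This is the coherent reading of an affine model bias — the model distorts
its own future climate exactly as it distorts its historical climate — and
it makes the recovery property exact: an ideal correction returns the
historical series to the reference distribution *and* returns δ in corrected
units. The tests verify both (KS distance < 0.02 at n = 10⁴; δ recovered
within 0.05 kPa).

## Exceedance and exposure

An exceedance day has daily VPD **strictly greater** than the cell's
threshold (boundary days are measure-zero in continuous data). Thresholds
are painted from each stratum onto the cells its mask covers; cells outside
every stratum are missing, not zero. The climatology is the count divided by
the number of 365-day years; periods shorter than one full year are
rejected, as are change maps whose two climatologies were counted under
different threshold maps.

Density rasters (persons per cell, tonnes of aboveground biomass per cell)
arrive on a finer grid nesting an integer number of times in the climate
grid and are resampled with the **median of strictly positive fine cells**;
exact zeros are the missing-data convention of biomass products and are
omitted, and a block with no positive cell becomes missing rather than zero.
Exposure is the elementwise product of the change in annual exceedance days
with the resampled density, in person-days/year or tonne-days/year. Density
is interpreted as an amount per cell (not per km²), which is what makes the
product's units person-days; the exposure contract is linear in density, so
the absolute scale of the synthetic rasters is irrelevant.

## The synthetic world

All tests run against seeded generators on a 365-day no-leap calendar
(leap-day records fold to Feb 28 on ingest):

* **Climate** — air temperature = domain mean + annual sinusoid (phase
  flipped across the equator) + diurnal sinusoid + a shared regional AR(1)
  + a per-cell AR(1); dew point = temperature − a non-negative folded-normal
  depression, so T_d ≤ T holds pointwise by construction. Defaults (mean
  18 °C, annual amplitude 8 °C, diurnal 5 °C, lag-1 correlation 0.7) give
  daily-maximum VPD in the 0.5–3.5 kPa range where real forest thresholds
  sit. 24 steps/day emulates hourly reanalysis, 8 emulates 3-hourly GCM
  output.
* **Daily VPD with a known marginal** — an AR(1) started from its stationary
  distribution N(μ, σ²), clamped at 0. Clamping only moves mass below zero,
  so P(VPD > θ) for θ > 0 is exactly the Gaussian tail — the closed form the
  end-to-end exceedance checks use. Cells are independent, so Monte-Carlo
  standard errors are taken across cells.
* **Fire occurrence** — each cell-day burns independently with probability
  logit⁻¹(β₀ + β₁·VPD). The pipeline default (β₀ = −9.5, β₁ = 2) keeps the
  per-cell-day burn probability near 10⁻³: fires must be rare relative to
  cell-days, as in real burned-area records, or the 5-year exclusion empties
  the absence pool on small grids. Pre-period burn history for filter tests
  is uniform-random and independent of the law, so expected filter counts
  are exact.
* **Density rasters** — log-normal marginals with an independent Bernoulli
  mask of exact zeros emulating missing-data holes.

What the generators do **not** emulate: fire spread and contagion, fuel
accumulation and ignition sources, topography and wind, spatially correlated
fire clusters, realistic population projections, leap years, and any
covariance between fire occurrence and the density layers. Passing tests
therefore demonstrate that the estimators and transforms recover planted
structure under the stated stochastic model — not that the thresholds or
exposure numbers transfer to any real landscape.

## Numerical choices

* Logistic fit: IRLS, deviance tolerance 1e-8, max 100 iterations;
  separation handled before the optimiser can diverge.
* ROC: unique score thresholds, trapezoidal integration; ties half-weighted.
* Quantile mapping: 99 levels at k/(n+1); linear interior interpolation;
  additive edge extrapolation; clamp at 0 kPa.
* Nearest-cell matching: haversine on a 6371-km sphere; ties within 1e-6 km
  resolve to the lowest row-major index.
* Stage seeds: master seed + CRC-32 of the stage name, mod 2³¹, so any stage
  is independently reproducible and no stage reads ambient entropy.
* Problem sizes in the validation suite (10⁴-row fits, 20 replicates,
  28-year single-cell series, 6×6×4-year exceedance worlds, 4×4 pipeline
  worlds) are chosen so every planted quantity is resolved to well inside
  its tolerance while the whole suite runs in seconds.

## Known limitations

* Single-predictor model: no evaporation, soil moisture, wind or human
  activity; the threshold is a fuel-dryness proxy, not a fire forecast.
* The delta-method CI on a ratio can misbehave when β₁ is poorly resolved
  (near-flat response); such strata should be judged by their flags, not
  their intervals.
* Empirical quantile mapping is not trend-preserving; quantile-delta
  variants are out of scope.
* TIFF rasters carry their georeference as JSON metadata written by this
  package, not as full GeoTIFF tags.
* NetCDF output is classic NetCDF-3 (scipy backend): no compression and no
  groups.
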
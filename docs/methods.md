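# Methods

This note documents the models implemented in `phenogrid`, the numerical
choices, and what the synthetic study conditions do and do not establish.

## Phenology models

Both models predict the day of year (DOY, 1-based; leap years have
DOY 366) on which leaf onset occurs at a pixel, from daily mean air
temperature.

**Spring warming (SW).** Growing degree-days accumulate from a fixed
start day (default DOY 1) above a base temperature k (default 0 °C):

    GDD(t) = sum_{i=start}^{t} max(T_i - k, 0).

Onset is the first t with GDD(t) ≥ GDD_C. GDD_C is a per-pixel constant,
calibrated as the interannual mean of GDD evaluated at the observed onset
dates; its interannual sample standard deviation (ddof = 1) and the number
of contributing years are stored alongside. Pixels with no detected onset
in any calibration year remain uncalibrated — a state, not an error — and
are excluded from all downstream maps.

**Parallel chill (PC).** GDD accumulates identically, but the critical sum
decays with accumulated chilling:

    NCD(t)  = #{ days d from 1 November of the prior year to t : T_d < k' },
    GDD_C(t) = a + b·exp(c·NCD(t)),

with k′ = 5 °C, b = 1084 °C·day, c = −0.00904 per chilling day — the
published constants for the most chilling-sensitive species group — fixed
region-wide. Chilling uses a strict inequality (T < k′), threshold
crossing a non-strict one (GDD ≥ GDD_C), and the chilling count is
inclusive of the day being evaluated. The per-pixel offset *a* is the
interannual mean of GDD(onset) − b·exp(c·NCD(onset)). This sign convention
is forced by self-consistency: with it, the threshold at the observed
onset equals the observed GDD exactly, so noise-free calibration
round-trips are exact. There is no lower temperature cutoff for chilling:
every day below 5 °C counts.

Prediction searches the whole year (DOY 1–366). The detection cutoff
(DOY 200) is a property of the satellite green-up rule, not of the models,
so future predictions may legitimately fall later than DOY 200.

**Numerical tie-break.** The crossing comparison uses a relative slack of
1e-9 on the threshold. Calibration defines GDD_C (or the PC threshold) by
equality at the observed onset; averaging identical yearly values can
perturb that threshold by an ulp, which without slack would delay the
predicted crossing by a full day. Daily degree increments are at least
seven orders of magnitude larger than the slack, so no genuine comparison
is affected.

## Green-up detection

GRVI = (green − red)/(green + red) computed from surface reflectance.
Onset for a year is the start DOY of the first 8-day composite with
GRVI strictly greater than 0.05, provided that start DOY is ≤ 200
(inclusive cutoff — the conservative reading of "before DOY 200"); the
date assigned is the composite's start day, with no sub-composite
interpolation, because the observation has 8-day resolution and
interpolation would invent precision. Cloudy/no-data composites are
treated as not exceeding. Pixels that never satisfy the rule carry no
onset for that year.

## Temperature gridding

Station daily means are (1) reduced to sea level by adding
rate·elev/100 with rate = 0.6 K per 100 m, (2) interpolated on the target
grid, (3) re-elevated by subtracting the same bias at each cell's DEM
elevation. Steps 1 and 3 are exact inverses of each other, so the scheme
is unbiased wherever the true field is lapse-consistent.

The interpolant is a thin-plate-spline radial basis function with a
first-degree polynomial tail (`scipy.interpolate.RBFInterpolator`), fitted
globally to all stations of a day. The polynomial tail reproduces constant
and planar fields exactly. The `tension` parameter is the spline's
smoothing weight; the default (1e-10) makes the surface near-interpolating
(station residuals far below 0.01 °C), and larger values trade fidelity at
the stations for smoothness. Since the station set is fixed across days,
the spline system is factored once and solved for all days simultaneously.
At least `min_stations` (default 4) distinct station positions are
required per day; duplicate positions and missing station-days are hard
errors — no silent gap filling.

Temperature is interpolated on the station grid and transferred to the
finer phenology grid by nearest-neighbour refinement (each fine cell takes
its containing coarse cell's value); aggregation in the other direction is
the unmasked block mean. Only integer resolution ratios are supported.
Sea/void DEM cells are masked and carry no temperature or phenology.

## Delta-method downscaling

For each day of year d, the delta field is

    delta(d) = mean over baseline years of [ fine(d) − regrid(coarse(d)) ],

and a future day is downscaled as regrid(coarse) + delta(doy). A
day-of-year climatological delta (366 slots) is the only reading under
which a baseline-period difference can be "added to the daily data" of a
future period. If the baseline contains no leap day, slot 366 copies slot
365. No temporal smoothing of the delta is applied. Identities that follow
from linearity — feeding the coarse baseline climatology back reproduces
the fine baseline climatology, and a uniform coarse offset passes through
unchanged — are verified to float precision in the tests.

## Validation and scenarios

Leave-one-out: for each calibration year, the model is recalibrated
without that year's onset map and the held-out year is predicted; the
per-pixel RMSE is the root mean square of (predicted − observed) over the
evaluable years. Pixels with fewer than two detected years are excluded
and counted. The reported "fraction below threshold" statistic defaults to
an 8-day threshold. For a decadal mean, an independent-errors argument
scales a single-year RMSE by 1/√n (`decadal_rmse_of_mean`).

Scenario runs predict every year of each future decade with the calibrated
parameters and delta-downscaled temperatures, average per pixel over years
with a predicted onset (pixels with fewer than 5 valid years in a decade
are masked), and compare against the decadal mean of the *predicted*
baseline years, so change maps are model-vs-model. Regional summaries are
the unweighted mean and median over pixels valid in both decades (no
cos-latitude weighting; the study domains are small enough that area
weighting changes nothing material, and the option is exposed in the
configuration). Site extraction reports the containing pixel's parameters
as mean ± interannual standard deviation plus the decadal changes.

## Synthetic study conditions

The generator produces every input with known ground truth. Defaults —
the conditions under which the test suite and acceptance script run:

- **Grid**: 24×24 cells of 450″ (0.125°), origin 44°N 138°E, a masked
  ocean corner in the southeast (531 land cells); coarse climate-model
  grid 4× coarser (6×6).
- **Terrain**: four smooth Gaussian ridges scaled to a 1500 m maximum.
- **Climate**: annual-mean sea-level field = 9 °C at the domain centre,
  −1.0 °C per degree northward, +0.2 °C per degree eastward, plus a static
  smooth anomaly (0.5 °C amplitude, 1.0° width); seasonal cycle of ±11 °C
  with the coldest day near DOY 15; lapse 0.6 K/100 m; day-to-day regional
  anomaly N(0, 2²) °C plus a random daily gradient of 0.15 °C per degree.
  The anomaly is spatially smooth by construction, so reconstruction from
  a sparse network is a meaningful test rather than an impossible one.
- **Stations**: 25, on a jittered 5×5 grid of land cells — quasi-uniform,
  like the ~20-km real mesonets this emulates — sampling exact cell values.
  With this density the gridding recovers the truth field to < 0.05 °C;
  random placement would leave coverage holes several times worse.
- **Weather indexing**: temperature is a function of (year, DOY), with the
  Nov–Dec chilling window indexed by days-until-year-end. Leap years carry
  one extra sample rather than shifting the seasonal cycle — the
  fixed-length model-calendar convention — which makes GDD and NCD
  identical functions of DOY across years and hence makes the noise-free
  calibration → prediction round trip exact to the day.
- **Phenology truth**: a per-pixel SW (GDD_C*) or PC (a*) field increasing
  with local annual-mean temperature (25 and 18 °C·day per °C
  respectively), mirroring the observed acclimation of the warmth
  requirement to local climate.
- **Vegetation index**: logistic green-up from −0.1 to 0.6 with a 5-day
  transition, sampled at 8-day composites, N(0, 0.01²) noise — well under
  the 0.15 contrast at the 0.05 threshold, so detection failures must be
  constructed deliberately.
- **Climate model emulation**: block mean of the truth plus a smooth
  static bias (±1.5 °C scale); future decades reuse the anomaly streams of
  analog baseline years plus uniform warming offsets of +1.5 °C (2030s)
  and +3.2 °C (2090s), a mid-range transient warming trajectory for the
  region.
- **Years**: calibration 2001–2009 (9 years), delta baseline 1994–2003
  (both configurable), future decades 2030–2039 and 2090–2099, each
  generated with its preceding year so the PC model's prior-autumn
  chilling is available.

What passing tests show — and do not show. The synthetic world is smooth
and lapse-consistent by construction: it validates the machinery
(accumulation, calibration, validation, downscaling, detection) and the
qualitative physics (warming advances onset; chilling loss damps the PC
response), not performance on real imagery. Real data add mixed pixels,
cloud contamination, sub-station-scale weather, land-use change, and
species heterogeneity, none of which are emulated; the noise-injection
test shows only that a known error scale propagates through leave-one-out
validation as theory predicts (mean RMSE σ·√(n/(n−1)) for n years, ≈ 8.5
days for σ = 8, n = 9).

## Degenerate inputs and edge cases

- Station series with gaps or duplicate (station, date) rows are hard
  errors naming the station and date; no imputation is attempted.
- GRVI exactly at the threshold does not trigger detection (strict
  exceedance); a detection rule cutoff is inclusive of its DOY.
- Years lacking prior-autumn coverage are excluded from PC calibration
  with a logged warning rather than an error.
- An empty GRVI series yields "not detected" with a logged warning.
- Uncalibrated pixels raise on scalar prediction and propagate as nodata
  in gridded prediction.
- Onset rasters use −1 as nodata; all rasters are NetCDF with an explicit
  mask variable and cell-center georeferencing, and projected-CRS inputs
  are rejected with instructions to reproject.

## Problem sizes

The shipped configurations are desk-scale by design: the default world is
a 24×24 grid over 37 generated years (observed span plus two future
decades with pre-years), on which the complete pipeline — gridding,
downscaling, detection, calibration, two leave-one-out runs and two
scenario runs — completes in a few seconds; the full test suite and the
acceptance script each run in well under a minute on one CPU. All
randomness flows from a single integer seed, and every generated product
is bit-reproducible for a given seed.

## Known limitations

- Single region-wide (b, c) pair for the PC model; no species-specific
  parameter sets, no sequential-chill or unified-model variants.
- The GDD start day is a global constant (DOY 1); in warm regions a
  pixel-wise start day would likely fit better.
- No quantile mapping or variance scaling in the downscaling; a purely
  additive delta preserves the coarse model's day-to-day variance.
- Interpolation is global per day; with thousands of stations a windowed
  or partitioned solver would be needed.
- Regional summaries are unweighted pixel statistics by default.
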
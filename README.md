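# phenogrid

Gridded degree-day phenology modelling: calibrate leaf-onset models per
pixel from satellite green-up maps and station temperatures, validate them
by leave-one-out cross-validation, and project how much earlier spring
leaf onset will arrive under a warming climate.

## The problem

Spring leaf onset (leaf flush) of cool-temperate deciduous trees is a
temperature-driven event. Classical degree-day models predict it from the
accumulated warmth of late winter and spring, but in rugged terrain the
warmth requirement varies strongly from place to place, so a model
calibrated at a handful of field sites cannot capture the geography of
the response. `phenogrid` implements the pixel-wise alternative: every
~500-m pixel of a satellite-derived onset-date map gets its own
calibrated parameter, driven by daily temperature grids interpolated from
a dense station network, and the calibrated models are then run on
statistically downscaled climate-model output to map the future change in
onset date.

Two models bracket the uncertain role of winter chilling:

- **SW (spring warming)** — onset occurs when growing degree-days reach a
  fixed critical sum,

  GDD(t) = Σᵢ₌₁..t max(Tᵢ − k, 0),  onset at the first t with GDD(t) ≥ GDD_C,

  with base temperature k = 0 °C and accumulation from 1 January. GDD_C is
  calibrated per pixel as the interannual mean of GDD at the observed
  onset dates.

- **PC (parallel chill)** — the critical sum decays exponentially with the
  number of chilling days NCD(t), the count of days since 1 November with
  mean temperature below k′ = 5 °C:

  GDD_C(t) = a + b·exp(c·NCD(t)),  b = 1084, c = −0.00904.

  Winters with more chilling lower the spring-warmth requirement. The
  offset *a* is calibrated per pixel as the interannual mean of
  GDD(onset) − b·exp(c·NCD(onset)).

The SW model is chilling-insensitive and the PC model maximally
chilling-sensitive, so the pair brackets the plausible response: under
warming, reduced chilling raises the PC threshold and damps the advance
of onset relative to SW.

Around the models, the package provides the full supporting pipeline:

- **Temperature gridding** — station readings are reduced to sea level
  with a fixed lapse rate (0.6 K per 100 m), interpolated with a
  thin-plate spline (near-interpolating by default, smoothing exposed),
  and re-elevated on a DEM.
- **Delta-method downscaling** — a day-of-year climatology of
  (fine observed − regridded coarse model) differences over a baseline
  period is added to the coarse model's future daily fields, preserving
  the observed fine-scale topographic structure.
- **Green-up detection** — onset is the start day of the first 8-day
  composite whose green–red vegetation index GRVI = (G − R)/(G + R)
  strictly exceeds 0.05, no later than day of year 200; pixels that never
  cross are treated as having no onset that year.
- **Validation** — leave-one-out over the calibration years with
  per-pixel RMSE in days.
- **Synthetic data** — a seeded generator that emulates the station
  network, the coarse biased climate model with prescribed decadal
  warming, and GRVI trajectories produced by a known SW or PC process, so
  the whole chain runs and is verified without any downloads.

## Worked example

Calibrate and project on the default synthetic world (24×24 grid,
25 stations, 9 observed years, two 10-year future decades with +1.5 °C
and +3.2 °C warming):

```python
import numpy as np
import phenogrid as pg
from phenogrid.models import model_year_inputs
from phenogrid.onset import detect_onset_map
from phenogrid.pipeline import gridded_station_temperatures

cfg = pg.SynthConfig(seed=1)          # 24x24 grid, 25 stations, SW truth
data = pg.generate(cfg)

# 1. station records -> daily temperature grids
obs = gridded_station_temperatures(data.stations, data.dem, cfg.observed_years)

# 2. green-up detection from the 8-day GRVI composites
onsets = {y: detect_onset_map(v, s, y, data.dem.geom, mask=data.dem.mask)
          for y, (s, v) in data.grvi.items()}

# 3. per-pixel calibration over the 9 observed years
years = range(cfg.calib_years[0], cfg.calib_years[1] + 1)
temps = model_year_inputs(obs, years, include_prior_autumn=False)
sw = pg.calibrate_sw(onsets, temps)
print(f"calibrated pixels: {int(np.isfinite(sw.gddc).sum())}")
print(f"GDD_C range: {np.nanmin(sw.gddc):.0f}-{np.nanmax(sw.gddc):.0f} degC-day")

# 4. leave-one-out validation
val = pg.leave_one_out(onsets, temps, model="sw")
print(f"mean leave-one-out RMSE: {val.mean_rmse():.1f} days "
      f"({100 * val.fraction_below:.0f}% of pixels below 8 days)")

# 5. delta-downscale the coarse climate model and project the change
d0, d1 = cfg.delta_years
delta = pg.build_delta({y: obs[y] for y in range(d0, d1 + 1)},
                       data.coarse_baseline, data.dem.geom)
futures = {}
for label in cfg.decades:
    ds = pg.apply_delta_years(data.coarse_future[label], delta)
    futures[label] = model_year_inputs(ds, range(cfg.decades[label][0],
                                                 cfg.decades[label][1] + 1), False)
res = pg.run_scenario(sw, "sw", temps, futures)
print(res.summary.to_string(index=False))
```

Output:

```
calibrated pixels: 531
GDD_C range: 95-320 degC-day
mean leave-one-out RMSE: 2.1 days (100% of pixels below 8 days)
model decade  mean_change_days  median_change_days  n_pixels
   sw  2030s         -9.435175           -9.222222       531
   sw  2090s        -21.055137          -20.177778       531
```

531 of the 576 cells are land with a detectable green-up; their critical
degree-day sums span 95–320 °C·day, increasing with local annual-mean
temperature. The held-out-year prediction error is about 2 days per pixel
(the injected weather variability), and under the two warming decades the
spring-warming model advances onset by about 9 and 21 days on average
(negative change = earlier onset). Running the same scenario with
`pg.calibrate_pc` / `model="pc"` gives smaller advances (about −6 and
−11 days): the loss of chilling days partially offsets the extra spring
warmth.

## Command line

The same stages are available as subcommands that chain through files:

```sh
phenogrid synth --seed 42 --preset tiny --out fixture/
phenogrid interpolate-temp --config fixture/config.yaml \
    --stations fixture/stations.csv --dem fixture/dem.nc --out tmean/
phenogrid downscale --config fixture/config.yaml --fine tmean/ \
    --coarse fixture/coarse/ --out future/
phenogrid detect-onset --config fixture/config.yaml --grvi fixture/grvi/ --out onsets/
phenogrid calibrate --config fixture/config.yaml --onsets onsets/ --temps tmean/ --out params/
phenogrid validate  --config fixture/config.yaml --onsets onsets/ --temps tmean/ --out val/
phenogrid predict   --config fixture/config.yaml --params params/ \
    --baseline tmean/ --future future/ --out scenario/
phenogrid summarize --config fixture/config.yaml --params params/ \
    --scenario scenario/ --sites sites.csv --out sites_summary.csv
```

All outputs are deterministic under a fixed seed.

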
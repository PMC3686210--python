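import dataclasses

import numpy as np
import pandas as pd
import pytest

import phenogrid as pg
from phenogrid.onset import NOT_DETECTED, detect_onset_map
from phenogrid.pipeline import gridded_station_temperatures
from phenogrid.synth import (SynthConfig, make_climate_year, make_dem,
                             make_gcm, make_onsets, make_stations,
                             truth_parameter_field)

from conftest import calib_inputs


def test_generation_is_bit_deterministic():
    cfg = SynthConfig.tiny(seed=9)
    a = pg.generate(cfg)
    b = pg.generate(cfg)
    np.testing.assert_array_equal(a.dem.values[~a.dem.mask],
                                  b.dem.values[~b.dem.mask])
    y = cfg.calib_years[0]
    np.testing.assert_array_equal(a.truth_fine[y].values[:, ~a.dem.mask],
                                  b.truth_fine[y].values[:, ~b.dem.mask])
    np.testing.assert_array_equal(a.truth_onsets[y].doy, b.truth_onsets[y].doy)
    np.testing.assert_array_equal(a.grvi[y][1][:, ~a.dem.mask],
                                  b.grvi[y][1][:, ~b.dem.mask])


def test_different_seeds_differ():
    a = make_dem(SynthConfig.tiny(seed=1))
    b = make_dem(SynthConfig.tiny(seed=2))
    assert not np.array_equal(a.values[~a.mask], b.values[~b.mask])


def test_dem_flat_option_and_elevation_bound():
    flat = make_dem(SynthConfig.tiny(flat_dem=True))
    assert np.nanmax(flat.values) == 0.0
    ridged = make_dem(SynthConfig.tiny(max_elev=1200.0))
    assert np.nanmax(ridged.values) <= 1200.0
    assert np.nanmin(ridged.values) >= 0.0


def test_lapse_rate_cools_elevated_cells_exactly():
    """A cell is rate * elev / 100 degC colder than its sea-level twin."""
    cfg = SynthConfig.tiny(seed=3).noise_free()
    flat = make_climate_year(dataclasses.replace(cfg, flat_dem=True),
                             make_dem(dataclasses.replace(cfg, flat_dem=True)),
                             2001)
    dem = make_dem(cfg)
    ridged = make_climate_year(cfg, dem, 2001)
    land = ~dem.mask
    expected = 0.6 * dem.values[land] / 100.0
    diff = flat.values[:, land] - ridged.values[:, land]
    np.testing.assert_allclose(diff, np.broadcast_to(expected, diff.shape),
                               atol=1e-9)


def test_stations_sample_exact_truth_cells(synth_noisy):
    data = synth_noisy
    geom = data.dem.geom
    st = data.stations[0]
    i, j = geom.cell_index(st.lat, st.lon)
    assert not data.dem.mask[i, j]
    assert st.elev == data.dem.values[i, j]
    year = data.cfg.observed_years[0]
    sel = st.series.dates.year == year
    np.testing.assert_array_equal(st.series.values[sel],
                                  data.truth_fine[year].values[:, i, j])


def test_station_series_contiguous_over_observed_span(synth_noisy):
    st = synth_noisy.stations[3]
    years = synth_noisy.cfg.observed_years
    assert st.series.dates[0] == pd.Timestamp(f"{years[0]}-01-01")
    assert st.series.dates[-1] == pd.Timestamp(f"{years[-1]}-12-31")


def test_gcm_warming_offset_is_recorded_truth(synth_noisy):
    """A future coarse year minus its baseline analog equals the offset."""
    data = synth_noisy
    cfg = data.cfg
    label = "2030s"
    fy = cfg.decades[label][0]
    analog = cfg.analog_year(fy)
    fut = data.coarse_future[label][fy]
    base = data.coarse_baseline[analog]
    diff = fut.values[:, ~fut.mask] - base.values[:, ~base.mask]
    np.testing.assert_allclose(diff, cfg.warming[label], atol=1e-9)


def test_gcm_without_bias_is_block_mean():
    cfg = SynthConfig.tiny(seed=4, gcm_bias=0.0).noise_free()
    dem = make_dem(cfg)
    truth = {2001: make_climate_year(cfg, dem, 2001)}
    coarse = make_gcm(cfg, truth)[2001]
    from phenogrid.grids import regrid_stack
    block = regrid_stack(truth[2001], cfg.coarse_geom)
    np.testing.assert_allclose(coarse.values[:, ~coarse.mask],
                               block.values[:, ~block.mask], atol=1e-12)


def test_truth_onsets_fire_at_immediate_crossing_for_tiny_threshold():
    """With gddc* below the first warm day's degree sum, onset is DOY 1."""
    cfg = SynthConfig.tiny(seed=5, mean_temp=25.0, seasonal_amp=2.0,
                           gddc_base=0.01, gddc_per_degc=0.0,
                           gddc_lim=(0.01, 0.01)).noise_free()
    dem = make_dem(cfg)
    truth = {y: make_climate_year(cfg, dem, y)
             for y in range(cfg.calib_years[0] - 1, cfg.calib_years[1] + 1)}
    onsets, _ = make_onsets(cfg, dem, truth)
    om = onsets[cfg.calib_years[0]]
    assert (om.doy[om.detected] == cfg.start_doy).all()


def test_step_greenup_detected_at_first_composite_after_truth():
    """width -> 0, no noise: detection = first composite start >= onset."""
    cfg = SynthConfig.tiny(seed=6, grvi_width=0.0).noise_free()
    data = pg.generate(cfg)
    year = cfg.calib_years[0]
    starts, values = data.grvi[year]
    detected = detect_onset_map(values, starts, year, data.dem.geom,
                                mask=data.dem.mask)
    truth = data.truth_onsets[year]
    both = truth.detected & detected.detected
    expected = starts[np.searchsorted(starts, truth.doy[both])]
    np.testing.assert_array_equal(detected.doy[both], expected)
    # pixels whose truth never fires stay flat-low, hence undetected
    assert not detected.detected[truth.doy == NOT_DETECTED].any()


def test_truth_parameter_tracks_local_climate(synth_noisy):
    """Warmer pixels carry a larger warmth requirement (acclimation)."""
    data = synth_noisy
    from phenogrid.synth import annual_mean_temperature
    t_ann = annual_mean_temperature(data.cfg, data.dem)
    ok = np.isfinite(data.truth_param) & np.isfinite(t_ann)
    r = np.corrcoef(t_ann[ok], data.truth_param[ok])[0, 1]
    assert r > 0.9


def test_full_chain_station_route_reproduces_truth_onsets(synth_nf_sw):
    """Stations -> gridding -> calibration -> prediction, noise-free: the
    interpolated-temperature round trip reproduces every truth onset."""
    data = synth_nf_sw
    cfg = data.cfg
    obs = gridded_station_temperatures(data.stations, data.dem,
                                       cfg.observed_years)
    temps = calib_inputs(data, obs, False)
    params = pg.calibrate_sw(data.truth_onsets, temps)
    for year, om in data.truth_onsets.items():
        pred = pg.predict_map("sw", params, *temps[year])
        det = om.detected & np.isfinite(params.gddc)
        np.testing.assert_array_equal(pred[det], om.doy[det])
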
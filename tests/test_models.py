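import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phenogrid as pg
from phenogrid.grids import GridGeometry
from phenogrid.models import (calibrate_pc, calibrate_sw, gdd_series,
                              ncd_series, pc_threshold, predict_onset_pc,
                              predict_onset_sw)
from phenogrid.onset import OnsetMap

from conftest import calib_inputs


def _dates(year, ndays):
    return pd.date_range(f"{year}-01-01", periods=ndays)


def test_gdd_definition():
    doys, gdd = gdd_series(_dates(2001, 3), np.array([5.0, -2.0, 3.0]))
    np.testing.assert_array_equal(doys, [1, 2, 3])
    np.testing.assert_allclose(gdd, [5.0, 5.0, 8.0])


def test_gdd_floor_at_zero():
    _, gdd = gdd_series(_dates(2001, 4), np.array([-5.0, -0.1, 0.0, -3.0]))
    np.testing.assert_allclose(gdd, 0.0)


def test_gdd_pointwise_nonincreasing_in_base_temperature():
    temps = np.array([5.0, -2.0, 3.0])
    _, g0 = gdd_series(_dates(2001, 3), temps, k=0.0)
    _, g1 = gdd_series(_dates(2001, 3), temps, k=1.0)
    np.testing.assert_allclose(g0, [5, 5, 8])
    np.testing.assert_allclose(g1, [4, 4, 6])
    assert (g1 <= g0).all()


def test_gdd_requires_coverage_from_start_doy():
    dates = pd.date_range("2001-01-05", periods=10)
    with pytest.raises(ValueError, match="DOY 1"):
        gdd_series(dates, np.zeros(10))


def test_ncd_definition():
    dates = pd.date_range("2001-11-01", periods=3)
    dates = dates.append(pd.date_range("2002-01-01", periods=0))
    # ncd_series keys on the final calendar year; use a cross-year span
    dates = pd.date_range("2001-11-01", "2002-01-02")
    temps = np.full(len(dates), 10.0)
    temps[:3] = [4.0, 6.0, 4.0]
    sel_dates, ncd = ncd_series(dates, temps)
    np.testing.assert_array_equal(ncd[:3], [1, 1, 2])
    assert ncd[-1] == 2  # warm days add nothing


def test_ncd_strict_inequality_at_ceiling():
    dates = pd.date_range("2001-11-01", "2002-01-02")
    _, ncd = ncd_series(dates, np.full(len(dates), 5.0))
    assert (ncd == 0).all()


def test_ncd_requires_chill_start_coverage():
    dates = pd.date_range("2001-12-01", "2002-03-01")
    with pytest.raises(ValueError, match="2001-11-01"):
        ncd_series(dates, np.zeros(len(dates)))


@given(kp1=st.floats(-5, 10), dk=st.floats(0.1, 10), seed=st.integers(0, 99))
def test_ncd_nondecreasing_in_ceiling(kp1, dk, seed):
    dates = pd.date_range("2001-11-01", "2002-02-01")
    temps = np.random.default_rng(seed).normal(2, 6, len(dates))
    _, lo = ncd_series(dates, temps, kprime=kp1)
    _, hi = ncd_series(dates, temps, kprime=kp1 + dk)
    assert (hi >= lo).all()


def test_pc_threshold_values():
    assert pc_threshold(0, a=10.0) == pytest.approx(10.0 + 1084.0)
    # independent evaluation of the exponential at 100 chilling days
    assert pc_threshold(100, a=0.0) == pytest.approx(1084.0 * math.exp(-0.904))
    assert pc_threshold(100000, a=42.0) == pytest.approx(42.0, abs=1e-6)


def test_pc_threshold_strictly_decreasing_in_chilling():
    ncd = np.arange(0, 200)
    thr = pc_threshold(ncd, a=50.0)
    assert (np.diff(thr) < 0).all()


def test_predict_sw_first_crossing():
    dates = _dates(2001, 4)
    temps = np.array([5.0, -2.0, 3.0, 4.0])
    assert predict_onset_sw(dates, temps, gddc=8.0) == 3
    assert predict_onset_sw(dates, temps, gddc=12.0) == 4
    assert predict_onset_sw(dates, temps, gddc=12.5) is None


def test_predict_sw_uncalibrated_pixel_is_error():
    with pytest.raises(ValueError, match="uncalibrated"):
        predict_onset_sw(_dates(2001, 4), np.ones(4), gddc=np.nan)


def test_predict_sw_warming_never_delays():
    rng = np.random.default_rng(0)
    dates = pd.date_range("2001-01-01", "2001-12-31")
    doy = np.arange(len(dates))
    temps = -8 * np.cos(2 * np.pi * (doy - 15) / 365) + rng.normal(0, 2, len(dates)) + 4
    base = predict_onset_sw(dates, temps, gddc=300.0)
    warm = predict_onset_sw(dates, temps + 1.0, gddc=300.0)
    assert base is not None and warm is not None and warm <= base


def test_predict_pc_reduces_to_sw_without_chilling():
    """A winter pinned just above k' gives NCD = 0, so GDD_C = b."""
    dates = pd.date_range("2000-11-01", "2001-12-31")
    temps = np.full(len(dates), 5.0)  # exactly k': never chilling, GDD grows
    in_year = dates.year == 2001
    pc = predict_onset_pc(dates, temps, a=0.0)
    sw = predict_onset_sw(dates[in_year], temps[in_year], gddc=1084.0)
    assert pc == sw


def test_predict_pc_more_chilling_never_delays():
    """Extra chilling in the prior autumn (outside the GDD window) lowers
    the threshold, so onset can only move earlier."""
    dates = pd.date_range("2000-11-01", "2001-12-31")
    doy_idx = np.arange(len(dates))
    base = 10.0 + 8.0 * np.sin(2 * np.pi * (doy_idx - 150) / 365)
    cold = base.copy()
    cold[:61] = -5.0  # Nov-Dec: 61 chilling days
    mild = base.copy()
    mild[:61] = 6.0  # Nov-Dec: no chilling; Jan onwards identical
    o_cold = predict_onset_pc(dates, cold, a=100.0)
    o_mild = predict_onset_pc(dates, mild, a=100.0)
    assert o_cold is not None
    assert o_mild is None or o_cold <= o_mild


def _onemap(doy, year=2001):
    geom = GridGeometry(1, 1, 43.0, 140.0, 900.0)
    return OnsetMap(year, geom, np.array([[doy]], np.int32))


def test_calibrate_sw_single_year_matches_gdd_at_onset():
    dates = _dates(2001, 4)
    temps = np.array([5.0, -2.0, 3.0, 4.0])[:, None, None]
    params = calibrate_sw({2001: _onemap(3)}, {2001: (dates, temps)})
    assert params.gddc[0, 0] == pytest.approx(8.0)
    assert params.n_years[0, 0] == 1
    assert np.isnan(params.std[0, 0])


def test_calibrate_sw_interannual_mean_and_sd():
    # two years engineered to give yearly GDD_C of 200 and 230
    d1, d2 = _dates(2001, 2), _dates(2002, 2)
    t1 = np.array([100.0, 100.0])[:, None, None]
    t2 = np.array([100.0, 130.0])[:, None, None]
    onsets = {2001: _onemap(2, 2001), 2002: _onemap(2, 2002)}
    params = calibrate_sw(onsets, {2001: (d1, t1), 2002: (d2, t2)})
    assert params.gddc[0, 0] == pytest.approx(215.0)
    assert params.std[0, 0] == pytest.approx(np.std([200.0, 230.0], ddof=1))
    assert params.std[0, 0] == pytest.approx(21.2, abs=0.05)


def test_calibrate_pc_offset_sign_and_magnitude():
    """a = GDD(onset) - b*exp(c*NCD(onset)); for GDD 215 at NCD 170 the
    offset is slightly negative, the pattern reported for cold sites."""
    dates = pd.date_range("2000-11-01", "2001-12-31")
    temps = np.zeros(len(dates))
    # 170 chilling days: cold from 1 Nov through 19 Apr (61 + 109 days)
    temps[:170] = -1.0
    temps[170:] = 10.0  # warm, non-chilling
    # onset on the day GDD reaches 215: 21.5 warm days after DOY 109
    in2001 = dates.year == 2001
    doys, gdd = gdd_series(dates[in2001], temps[in2001])
    onset_doy = int(doys[np.argmax(gdd >= 215.0)])
    om = _onemap(onset_doy)
    params = calibrate_pc({2001: (om)}, {2001: (dates, temps[:, None, None])})
    gdd_at_onset = float(gdd[onset_doy - 1])
    expected = gdd_at_onset - 1084.0 * math.exp(-0.00904 * 170)
    assert params.a[0, 0] == pytest.approx(expected)
    assert expected == pytest.approx(220.0 - 233.14, abs=0.2)


def test_calibrate_pc_exact_cancellation():
    """NCD(onset) = 0 and GDD(onset) = 1084 force a = 0."""
    dates = pd.date_range("2000-11-01", "2001-12-31")
    temps = np.full(len(dates), 10.84)  # never chilling; GDD(100) = 1084
    om = _onemap(100)
    params = calibrate_pc({2001: om}, {2001: (dates, temps[:, None, None])})
    assert params.a[0, 0] == pytest.approx(0.0, abs=1e-9)


def test_calibrate_pc_excludes_years_missing_prior_autumn(caplog):
    dates_short = pd.date_range("2001-01-01", "2001-12-31")
    dates_full = pd.date_range("2001-11-01", "2002-12-31")
    temps_s = np.full((len(dates_short), 1, 1), 6.0)
    temps_f = np.full((len(dates_full), 1, 1), 6.0)
    onsets = {2001: _onemap(100, 2001), 2002: _onemap(100, 2002)}
    with caplog.at_level("WARNING"):
        params = calibrate_pc(
            onsets, {2001: (dates_short, temps_s), 2002: (dates_full, temps_f)}
        )
    assert params.n_years[0, 0] == 1
    assert "2001" in caplog.text


def test_predictors_agree_with_exhaustive_scan(rng):
    """Vectorised predictors equal a day-by-day scan on random pixel-years."""
    mismatches = 0
    for _ in range(200):
        year = 2001 + int(rng.integers(0, 9))
        dates = pd.date_range(f"{year - 1}-11-01", f"{year}-12-31")
        n = len(dates)
        temps = (rng.normal(6.0, 5.0, n)
                 - 10.0 * np.cos(2 * np.pi * np.arange(n) / 365.0))
        gddc = float(rng.uniform(50, 800))
        a = float(rng.uniform(-100, 200))
        gdd = 0.0
        ncd = 0
        scan_sw = scan_pc = None
        for ts, t in zip(dates, temps):
            if t < 5.0:
                ncd += 1
            if ts.year == year:
                gdd += max(t, 0.0)
                if scan_sw is None and gdd >= gddc:
                    scan_sw = ts.dayofyear
                if scan_pc is None and gdd >= a + 1084.0 * math.exp(-0.00904 * ncd):
                    scan_pc = ts.dayofyear
        in_year = dates.year == year
        if predict_onset_sw(dates[in_year], temps[in_year], gddc) != scan_sw:
            mismatches += 1
        if predict_onset_pc(dates, temps, a) != scan_pc:
            mismatches += 1
    assert mismatches == 0


def test_noise_free_roundtrip_recovers_generator(synth_nf_sw, synth_nf_pc):
    """Calibrating on truth onsets reproduces them exactly and recovers the
    generating parameter field to within one day's degree increment."""
    for data, model in ((synth_nf_sw, "sw"), (synth_nf_pc, "pc")):
        temps = calib_inputs(data, data.truth_fine, model == "pc")
        if model == "sw":
            params = pg.calibrate_sw(data.truth_onsets, temps)
            value, truth = params.gddc, data.truth_param
        else:
            params = pg.calibrate_pc(data.truth_onsets, temps)
            value, truth = params.a, data.truth_param
        ok = np.isfinite(value)
        assert ok.sum() > 400
        err = value[ok] - truth[ok]
        assert (err >= -1e-6).all()  # calibration can only overshoot
        assert np.max(err) < 16.0  # bounded by one spring day's warmth
        for year, om in data.truth_onsets.items():
            dates, values = temps[year]
            pred = pg.predict_map(model, params, dates, values)
            det = om.detected & ok
            np.testing.assert_array_equal(pred[det], om.doy[det])
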
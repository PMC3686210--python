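"""Spring-warming (SW) and parallel-chill (PC) degree-day onset models.

SW: growing degree-days GDD(t) = sum_{i=start_doy}^{t} max(T_i - k, 0)
accumulate from 1 January (k = 0 degC by default); leaf onset is the first
DOY at which GDD reaches a per-pixel critical sum GDD_C.

PC: the critical sum is not constant but decays exponentially with the
number of chilling days NCD(t) = #{days since 1 November of the previous
year with T < k'} (k' = 5 degC):

    GDD_C(t) = a + b * exp(c * NCD(t)),   b = 1084, c = -0.00904

so winters with more chilling lower the spring-warmth requirement.  The
per-pixel offset ``a`` is the interannual mean of
GDD(onset) - b*exp(c*NCD(onset)) over the calibration years, which makes
the threshold self-consistent at the observed onset dates.

All functions take time along axis 0 and accept either a single pixel
(1-D temperatures) or a grid stack (3-D), so pixel-level worked examples
and gridded calibration share one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import DailyStack, GridGeometry
from .onset import NOT_DETECTED, OnsetMap

logger = logging.getLogger(__name__)

NO_ONSET = -1

# Relative slack for the GDD >= GDD_C comparison.  Calibration defines the
# threshold by equality at the observed onset, so round-off (e.g. averaging
# identical yearly values) must not be able to push the crossing a day
# later.  Daily degree increments are many orders of magnitude larger.
_CROSSING_RTOL = 1e-9


def _reached(gdd, threshold):
    tol = _CROSSING_RTOL * (1.0 + np.abs(threshold))
    return gdd >= threshold - tol


@dataclass
class SWParams:
    """Calibrated spring-warming parameters (per pixel)."""

    gddc: np.ndarray  # degC-day; NaN where uncalibrated
    std: np.ndarray  # sample sd of yearly GDD_C; NaN where n < 2
    n_years: np.ndarray  # detected years used per pixel
    k: float = 0.0
    start_doy: int = 1


@dataclass
class PCParams:
    """Calibrated parallel-chill parameters (per pixel)."""

    a: np.ndarray  # degC-day offset; NaN where uncalibrated
    std: np.ndarray
    n_years: np.ndarray
    kprime: float = 5.0
    b: float = 1084.0
    c: float = -0.00904
    k: float = 0.0
    start_doy: int = 1
    chill_start: tuple[int, int] = (11, 1)  # month, day of preceding year


def _as_time_series(dates, temps) -> tuple[pd.DatetimeIndex, np.ndarray]:
    dates = pd.DatetimeIndex(dates)
    temps = np.asarray(temps, dtype=float)
    if temps.shape[0] != len(dates):
        raise ValueError("temperature axis 0 must match the dates")
    return dates, temps


def gdd_series(dates, temps, k: float = 0.0, start_doy: int = 1):
    """Cumulative growing degree-days over the final calendar year.

    Returns ``(doys, gdd)`` where ``doys`` runs from ``start_doy`` to the
    last covered DOY of the year and ``gdd[i]`` is the sum of
    max(T - k, 0) from ``start_doy`` through ``doys[i]`` (so the sum just
    before ``start_doy`` is zero).
    """
    dates, temps = _as_time_series(dates, temps)
    year = dates[-1].year
    in_year = dates.year == year
    doys_all = dates.dayofyear.to_numpy()
    sel = in_year & (doys_all >= start_doy)
    if not sel.any() or doys_all[sel][0] != start_doy:
        raise ValueError(
            f"series must cover DOY {start_doy} of {year} onwards"
        )
    gdd = np.cumsum(np.clip(temps[sel] - k, 0.0, None), axis=0)
    return doys_all[sel], gdd


def ncd_series(dates, temps, kprime: float = 5.0,
               chill_start: tuple[int, int] = (11, 1)):
    """Cumulative chilling-day count from the chill start date.

    The chilling clock starts on 1 November (by default) of the year
    preceding the final calendar year in ``dates``; a chilling day is one
    with mean temperature strictly below ``kprime``.  Returns
    ``(sel_dates, ncd)`` with the count inclusive of each day.
    """
    dates, temps = _as_time_series(dates, temps)
    year = dates[-1].year
    start = pd.Timestamp(year - 1, *chill_start)
    if dates[0] > start:
        raise ValueError(
            f"series must begin at or before the chilling start {start.date()}"
        )
    sel = dates >= start
    ncd = np.cumsum(temps[sel] < kprime, axis=0)
    return dates[sel], ncd


def pc_threshold(ncd, a, b: float = 1084.0, c: float = -0.00904):
    """Chilling-dependent critical degree-day sum a + b*exp(c*NCD)."""
    if np.ndim(a) == 0 and not np.isfinite(a):
        raise ValueError("offset a must be finite")
    return a + b * np.exp(c * np.asarray(ncd, dtype=float))


def _first_crossing(doys: np.ndarray, reached: np.ndarray):
    """First DOY (along axis 0) where ``reached`` is True; NO_ONSET if never."""
    hit = reached.any(axis=0)
    idx = reached.argmax(axis=0)
    onset = np.where(hit, doys[idx], NO_ONSET)
    return onset.astype(np.int32)


def predict_onset_sw(dates, temps, gddc, k: float = 0.0, start_doy: int = 1):
    """Predicted SW onset: smallest DOY with GDD(t) >= GDD_C.

    For 1-D temperatures, ``gddc`` is a scalar and the result is an int
    DOY or ``None`` (no onset this year).  For 3-D stacks, ``gddc`` is a
    per-pixel array and the result is an int array with -1 for no onset;
    NaN (uncalibrated) pixels yield -1.
    """
    doys, gdd = gdd_series(dates, temps, k=k, start_doy=start_doy)
    scalar = gdd.ndim == 1
    if scalar:
        if not np.isfinite(gddc):
            raise ValueError("uncalibrated pixel: GDD_C undefined")
        onset = _first_crossing(doys, _reached(gdd, gddc))
        return int(onset) if onset != NO_ONSET else None
    gddc = np.asarray(gddc, dtype=float)
    with np.errstate(invalid="ignore"):
        reached = _reached(gdd, gddc)
    reached &= np.isfinite(gddc)
    return _first_crossing(doys, reached)


def predict_onset_pc(dates, temps, a, kprime: float = 5.0,
                     b: float = 1084.0, c: float = -0.00904,
                     k: float = 0.0, start_doy: int = 1,
                     chill_start: tuple[int, int] = (11, 1)):
    """Predicted PC onset: smallest DOY with GDD(t) >= a + b*exp(c*NCD(t)).

    GDD accumulates exactly as in the SW model; only the threshold varies
    with the chilling count, so the series must span the prior autumn.
    """
    dates = pd.DatetimeIndex(dates)
    doys, gdd = gdd_series(dates, temps, k=k, start_doy=start_doy)
    ncd_dates, ncd = ncd_series(dates, temps, kprime=kprime,
                                chill_start=chill_start)
    year = dates[-1].year
    in_year = (ncd_dates.year == year) & (ncd_dates.dayofyear >= start_doy)
    ncd_year = ncd[in_year]
    scalar = gdd.ndim == 1
    if scalar:
        if not np.isfinite(a):
            raise ValueError("uncalibrated pixel: offset a undefined")
        thr = pc_threshold(ncd_year, a, b, c)
        onset = _first_crossing(doys, _reached(gdd, thr))
        return int(onset) if onset != NO_ONSET else None
    a = np.asarray(a, dtype=float)
    thr = a + b * np.exp(c * ncd_year.astype(float))
    with np.errstate(invalid="ignore"):
        reached = _reached(gdd, thr)
    reached &= np.isfinite(a)
    return _first_crossing(doys, reached)


def _yearly_stat(per_year: list[np.ndarray], geom_shape) -> tuple[np.ndarray, ...]:
    """Mean, sample sd, and count over a list of per-year 2-D arrays."""
    stackv = np.stack(per_year) if per_year else np.empty((0, *geom_shape))
    finite = np.isfinite(stackv)
    n = finite.sum(axis=0)
    filled = np.where(finite, stackv, 0.0)
    mean = np.where(n > 0, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
    sq = np.where(finite, (stackv - mean) ** 2, 0.0)
    std = np.where(n > 1, np.sqrt(sq.sum(axis=0) / np.maximum(n - 1, 1)), np.nan)
    return mean, std, n


def _gdd_at_onset(dates, temps, onset: OnsetMap, k: float, start_doy: int):
    """Per-pixel GDD at the observed onset DOY (NaN where undetected)."""
    doys, gdd = gdd_series(dates, temps, k=k, start_doy=start_doy)
    doy_map = onset.doy
    valid = doy_map != NOT_DETECTED
    if valid.any() and (doy_map[valid] > doys[-1]).any():
        raise ValueError("onset DOY beyond the temperature series")
    idx = np.clip(doy_map - start_doy, 0, len(doys) - 1)
    picked = np.take_along_axis(gdd, idx[None, :, :], axis=0)[0]
    return np.where(valid, picked, np.nan), valid


def calibrate_sw(onsets: dict[int, OnsetMap],
                 temps: dict[int, tuple[pd.DatetimeIndex, np.ndarray]],
                 k: float = 0.0, start_doy: int = 1) -> SWParams:
    """Per-pixel GDD_C: interannual mean of GDD at the observed onset.

    ``temps[year]`` is a ``(dates, values)`` pair covering the calendar
    year; ``onsets[year]`` the observed onset map.  Pixels with no
    detected year stay uncalibrated (NaN), which is a state, not an error.
    """
    if not onsets:
        raise ValueError("no onset maps supplied")
    shape = next(iter(onsets.values())).geom.shape
    per_year = []
    for year in sorted(onsets):
        if year not in temps:
            logger.warning("year %d excluded: no temperature data", year)
            continue
        dates, values = temps[year]
        gddc_y, _ = _gdd_at_onset(dates, values, onsets[year], k, start_doy)
        per_year.append(gddc_y)
    mean, std, n = _yearly_stat(per_year, shape)
    return SWParams(gddc=mean, std=std, n_years=n, k=k, start_doy=start_doy)


def calibrate_pc(onsets: dict[int, OnsetMap],
                 temps: dict[int, tuple[pd.DatetimeIndex, np.ndarray]],
                 kprime: float = 5.0, b: float = 1084.0, c: float = -0.00904,
                 k: float = 0.0, start_doy: int = 1,
                 chill_start: tuple[int, int] = (11, 1)) -> PCParams:
    """Per-pixel offset a: interannual mean of GDD(onset) - b*exp(c*NCD(onset)).

    Years whose series does not reach back to the chilling start (prior
    autumn missing) are excluded with a logged warning.
    """
    if not onsets:
        raise ValueError("no onset maps supplied")
    shape = next(iter(onsets.values())).geom.shape
    per_year = []
    for year in sorted(onsets):
        if year not in temps:
            logger.warning("year %d excluded: no temperature data", year)
            continue
        dates, values = temps[year]
        dates = pd.DatetimeIndex(dates)
        start = pd.Timestamp(year - 1, *chill_start)
        if dates[0] > start:
            logger.warning(
                "year %d excluded from PC calibration: series starts %s, "
                "after the chilling start %s",
                year, dates[0].date(), start.date(),
            )
            continue
        gdd_on, valid = _gdd_at_onset(dates, values, onsets[year], k, start_doy)
        ncd_dates, ncd = ncd_series(dates, values, kprime=kprime,
                                    chill_start=chill_start)
        in_year = (ncd_dates.year == year) & (ncd_dates.dayofyear >= start_doy)
        ncd_year = ncd[in_year]
        doy_map = onsets[year].doy
        idx = np.clip(doy_map - start_doy, 0, ncd_year.shape[0] - 1)
        ncd_on = np.take_along_axis(ncd_year, idx[None, :, :], axis=0)[0]
        a_y = gdd_on - b * np.exp(c * ncd_on.astype(float))
        per_year.append(np.where(valid, a_y, np.nan))
    if not per_year:
        raise ValueError("no year had prior-autumn coverage for PC calibration")
    mean, std, n = _yearly_stat(per_year, shape)
    return PCParams(a=mean, std=std, n_years=n, kprime=kprime, b=b, c=c,
                    k=k, start_doy=start_doy, chill_start=chill_start)


def assemble_model_year(stacks: dict[int, DailyStack], year: int,
                        include_prior_autumn: bool = False,
                        chill_start: tuple[int, int] = (11, 1)):
    """Concatenate calendar-year stacks into one model-year series.

    Returns ``(dates, values)`` covering the calendar year, optionally
    prefixed with the prior year's days from the chilling start onward.
    """
    if year not in stacks:
        raise KeyError(f"no temperature stack for year {year}")
    this = stacks[year]
    if not include_prior_autumn:
        return this.dates, this.values
    prev = stacks.get(year - 1)
    if prev is None:
        raise KeyError(f"no temperature stack for prior autumn of {year}")
    start = pd.Timestamp(year - 1, *chill_start)
    sel = prev.dates >= start
    dates = prev.dates[sel].append(this.dates)
    values = np.concatenate([prev.values[sel], this.values], axis=0)
    return dates, values


def model_year_inputs(stacks: dict[int, DailyStack], years,
                      include_prior_autumn: bool,
                      chill_start: tuple[int, int] = (11, 1)) -> dict:
    """Build the {year: (dates, values)} mapping the calibrators expect."""
    out = {}
    for year in years:
        try:
            out[year] = assemble_model_year(stacks, year,
                                            include_prior_autumn, chill_start)
        except KeyError as err:
            if include_prior_autumn:
                logger.warning("skipping %d: %s", year, err)
            else:
                raise
    return out
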
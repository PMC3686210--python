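"""Leave-one-out validation, future scenarios, and regional summaries."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridGeometry
from .models import (NO_ONSET, PCParams, SWParams, calibrate_pc, calibrate_sw,
                     predict_onset_pc, predict_onset_sw)
from .onset import NOT_DETECTED, OnsetMap

logger = logging.getLogger(__name__)


@dataclass
class ValidationResult:
    """Per-pixel leave-one-out RMSE (days) and the underlying error maps."""

    model: str
    geom: GridGeometry
    rmse: np.ndarray  # days; NaN where not evaluable
    error_maps: dict[int, np.ndarray]  # year -> predicted - observed (days)
    n_excluded: int  # pixels with < 2 detected years
    threshold: float = 8.0

    @property
    def fraction_below(self) -> float:
        """Fraction of evaluated pixels with RMSE below the threshold."""
        evaluated = np.isfinite(self.rmse)
        if not evaluated.any():
            return float("nan")
        return float((self.rmse[evaluated] < self.threshold).mean())

    def mean_rmse(self) -> float:
        return float(np.nanmean(self.rmse))


def predict_map(model: str, params, dates, values) -> np.ndarray:
    """Gridded onset prediction for one year under either model."""
    if model == "sw":
        assert isinstance(params, SWParams)
        return predict_onset_sw(dates, values, params.gddc,
                                k=params.k, start_doy=params.start_doy)
    if model == "pc":
        assert isinstance(params, PCParams)
        return predict_onset_pc(dates, values, params.a, kprime=params.kprime,
                                b=params.b, c=params.c, k=params.k,
                                start_doy=params.start_doy,
                                chill_start=params.chill_start)
    raise ValueError(f"unknown model {model!r}; expected 'sw' or 'pc'")


def _calibrate(model: str, onsets, temps, **kw):
    return calibrate_sw(onsets, temps, **kw) if model == "sw" \
        else calibrate_pc(onsets, temps, **kw)


def leave_one_out(onsets: dict[int, OnsetMap],
                  temps: dict[int, tuple[pd.DatetimeIndex, np.ndarray]],
                  model: str = "sw", threshold: float = 8.0,
                  **model_kw) -> ValidationResult:
    """Hold out each year, calibrate on the rest, and score the prediction.

    For every year the model is recalibrated without that year's onset
    map, the held-out year is predicted, and the error (predicted minus
    observed, days) is recorded.  The per-pixel RMSE is the root mean
    square over the evaluable years.  Pixels with fewer than two detected
    years cannot be evaluated and are counted in ``n_excluded``.
    """
    years = sorted(set(onsets) & set(temps))
    if len(years) < 2:
        raise ValueError("leave-one-out needs at least two years")
    geom = onsets[years[0]].geom
    detected_count = sum((onsets[y].doy != NOT_DETECTED).astype(int)
                        for y in years)
    error_maps: dict[int, np.ndarray] = {}
    for y in years:
        rest_onsets = {yy: onsets[yy] for yy in years if yy != y}
        params = _calibrate(model, rest_onsets, temps, **model_kw)
        dates, values = temps[y]
        predicted = predict_map(model, params, dates, values)
        observed = onsets[y].doy
        ok = (observed != NOT_DETECTED) & (predicted != NO_ONSET)
        err = np.where(ok, predicted - observed, np.nan).astype(float)
        error_maps[y] = err
    errs = np.stack([error_maps[y] for y in years])
    finite = np.isfinite(errs)
    n_eval = finite.sum(axis=0)
    sumsq = np.where(finite, errs**2, 0.0).sum(axis=0)
    rmse = np.where(n_eval > 0, np.sqrt(sumsq / np.maximum(n_eval, 1)), np.nan)
    excluded = int((detected_count < 2).sum())
    rmse = np.where(detected_count >= 2, rmse, np.nan)
    logger.info("leave-one-out (%s): %d pixels excluded (<2 detected years)",
                model, excluded)
    return ValidationResult(model=model, geom=geom, rmse=rmse,
                            error_maps=error_maps, n_excluded=excluded,
                            threshold=threshold)


def decadal_rmse_of_mean(single_year_rmse: float, n_years: int) -> float:
    """RMSE of a decadal-mean onset from a single-year RMSE.

    Assumes errors independent between years, so the error of an
    ``n``-year mean shrinks by ``sqrt(n)``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if single_year_rmse < 0:
        raise ValueError("RMSE must be >= 0")
    return single_year_rmse / math.sqrt(n_years)


@dataclass
class ScenarioResult:
    """Decadal-mean onset for baseline and futures, with change maps."""

    model: str
    geom: GridGeometry | None
    baseline_mean: np.ndarray  # mean onset DOY; NaN where invalid
    decade_means: dict[str, np.ndarray] = field(default_factory=dict)
    change: dict[str, np.ndarray] = field(default_factory=dict)  # days
    summary: pd.DataFrame | None = None


def _decadal_mean(predictions: list[np.ndarray], min_valid: int) -> np.ndarray:
    stack = np.stack(predictions).astype(float)
    stack[stack == NO_ONSET] = np.nan
    finite = np.isfinite(stack)
    n_valid = finite.sum(axis=0)
    mean = np.where(finite, stack, 0.0).sum(axis=0) / np.maximum(n_valid, 1)
    return np.where(n_valid >= min_valid, mean, np.nan)


def run_scenario(params, model: str,
                 baseline_temps: dict[int, tuple],
                 future_decades: dict[str, dict[int, tuple]],
                 min_valid_years: int = 5,
                 geom: GridGeometry | None = None) -> ScenarioResult:
    """Predict decadal-mean onset for the baseline and each future decade.

    ``change[label] = future mean - baseline mean`` (days; negative =
    earlier onset), defined only where both decadal means are valid.
    The summary table reports the unweighted regional mean and median
    change over valid pixels.
    """
    geom_shape = np.shape(params.gddc if model == "sw" else params.a)
    base_preds = [predict_map(model, params, *baseline_temps[y])
                  for y in sorted(baseline_temps)]
    min_base = min(min_valid_years, len(base_preds))
    baseline_mean = _decadal_mean(base_preds, min_base)
    result = ScenarioResult(model=model, geom=geom, baseline_mean=baseline_mean)
    rows = []
    for label in sorted(future_decades):
        decade = future_decades[label]
        expected = range(min(decade), max(decade) + 1)
        missing = [y for y in expected if y not in decade]
        if missing:
            raise ValueError(f"decade {label} missing years {missing}")
        preds = [predict_map(model, params, *decade[y]) for y in sorted(decade)]
        dec_mean = _decadal_mean(preds, min(min_valid_years, len(preds)))
        change = dec_mean - baseline_mean  # NaN propagates where invalid
        result.decade_means[label] = dec_mean
        result.change[label] = change
        valid = np.isfinite(change)
        rows.append({
            "model": model,
            "decade": label,
            "mean_change_days": float(np.mean(change[valid])) if valid.any() else np.nan,
            "median_change_days": float(np.median(change[valid])) if valid.any() else np.nan,
            "n_pixels": int(valid.sum()),
        })
    result.summary = pd.DataFrame(rows)
    assert np.shape(baseline_mean) == geom_shape
    return result


def summarize_sites(sites: list[tuple[str, float, float]],
                    geom: GridGeometry,
                    sw: SWParams | None = None,
                    pc: PCParams | None = None,
                    scenarios: dict[str, ScenarioResult] | None = None
                    ) -> pd.DataFrame:
    """Extract calibrated parameters and onset changes at point sites.

    One row per site, reporting the containing pixel's GDD_C and ``a``
    as mean +/- interannual standard deviation, plus the decadal onset
    changes if scenario results are given.  A site outside the grid is an
    error naming the site; a site on an uncalibrated pixel is flagged.
    """
    rows = []
    for name, lat, lon in sites:
        if not geom.contains(lat, lon):
            raise ValueError(f"site {name} ({lat}, {lon}) outside the grid extent")
        i, j = geom.cell_index(lat, lon)
        row: dict = {"site": name, "lat": lat, "lon": lon, "row": i, "col": j}
        calibrated = True
        if sw is not None:
            row["gddc"] = float(sw.gddc[i, j])
            row["gddc_std"] = float(sw.std[i, j])
            row["n_years_sw"] = int(sw.n_years[i, j])
            calibrated &= bool(np.isfinite(sw.gddc[i, j]))
        if pc is not None:
            row["a"] = float(pc.a[i, j])
            row["a_std"] = float(pc.std[i, j])
            row["n_years_pc"] = int(pc.n_years[i, j])
            calibrated &= bool(np.isfinite(pc.a[i, j]))
        row["calibrated"] = calibrated
        if scenarios:
            for model, res in sorted(scenarios.items()):
                for label, change in sorted(res.change.items()):
                    row[f"change_{model}_{label}_days"] = float(change[i, j])
        rows.append(row)
    return pd.DataFrame(rows)
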
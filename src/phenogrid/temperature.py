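"""Station temperatures to daily gridded fields.

The gridding follows the classical three-step scheme: reduce each station
reading to an equivalent sea-level temperature with a fixed lapse rate
(0.6 K per 100 m), interpolate the sea-level field with a spline, and
re-elevate on the DEM by subtracting the same bias.  The spline is a
thin-plate radial basis function with a first-degree polynomial tail, so
constant and planar fields are reproduced exactly; the ``tension``
parameter is the smoothing weight (near zero = near-interpolating).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .grids import DailyStack, Grid, GridGeometry
from .stations import StationRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LapseModel:
    """Fixed linear lapse of temperature with elevation."""

    rate: float = 0.6  # K per 100 m

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("lapse rate must be >= 0")


@dataclass(frozen=True)
class InterpSettings:
    """Spline interpolation settings.

    tension: positive smoothing weight of the thin-plate spline
    (values near zero interpolate the stations almost exactly).
    min_stations: minimum number of reporting stations per day.
    """

    tension: float = 1e-10
    min_stations: int = 4

    def __post_init__(self) -> None:
        if self.tension <= 0:
            raise ValueError("tension must be positive")
        if self.min_stations < 3:
            raise ValueError("min_stations must be >= 3")


def to_sea_level(temp, elev, lapse: LapseModel = LapseModel()):
    """Reduce a temperature at elevation to its sea-level equivalent."""
    temp = np.asarray(temp, dtype=float)
    elev = np.asarray(elev, dtype=float)
    if not (np.isfinite(temp).all() and np.isfinite(elev).all()):
        raise ValueError("non-finite temperature or elevation")
    return temp + lapse.rate * elev / 100.0


def from_sea_level(temp, elev, lapse: LapseModel = LapseModel()):
    """Inverse of :func:`to_sea_level`: re-elevate a sea-level temperature."""
    temp = np.asarray(temp, dtype=float)
    elev = np.asarray(elev, dtype=float)
    if not (np.isfinite(temp).all() and np.isfinite(elev).all()):
        raise ValueError("non-finite temperature or elevation")
    return temp - lapse.rate * elev / 100.0


def _check_stations(lats: np.ndarray, lons: np.ndarray,
                    settings: InterpSettings, label: str) -> None:
    if len(lats) < settings.min_stations:
        raise ValueError(
            f"only {len(lats)} stations available for {label}; "
            f"need at least {settings.min_stations}"
        )
    pts = np.c_[lats, lons]
    _, counts = np.unique(pts, axis=0, return_counts=True)
    if (counts > 1).any():
        raise ValueError(f"coincident station positions for {label}")


def _fit_rbf(lats, lons, values, settings: InterpSettings) -> RBFInterpolator:
    return RBFInterpolator(
        np.c_[lats, lons],
        values,
        kernel="thin_plate_spline",
        smoothing=settings.tension,
        degree=1,
    )


def interpolate_day(lats, lons, values, target: GridGeometry,
                    settings: InterpSettings = InterpSettings(),
                    mask: np.ndarray | None = None,
                    label: str = "day") -> Grid:
    """Interpolate one day of sea-level station temperatures onto a grid."""
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    values = np.asarray(values, float)
    _check_stations(lats, lons, settings, label)
    if mask is None:
        mask = np.zeros(target.shape, bool)
    glat, glon = target.mesh()
    cells = np.c_[glat[~mask], glon[~mask]]
    out = np.full(target.shape, np.nan)
    out[~mask] = _fit_rbf(lats, lons, values, settings)(cells)
    return Grid(target, out, mask.copy())


def interpolate_days(lats, lons, values, target: GridGeometry,
                     settings: InterpSettings = InterpSettings(),
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Interpolate many days at once for a fixed station set.

    ``values`` has shape (n_stations, n_days).  Because the station
    positions are shared, the spline system is factored once.  Returns an
    array (n_days, nrows, ncols) with NaN outside the mask.
    """
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    values = np.asarray(values, float)
    _check_stations(lats, lons, settings, "batch")
    if not np.isfinite(values).all():
        raise ValueError("non-finite station values")
    if mask is None:
        mask = np.zeros(target.shape, bool)
    glat, glon = target.mesh()
    cells = np.c_[glat[~mask], glon[~mask]]
    fields = _fit_rbf(lats, lons, values, settings)(cells)  # (ncells, ndays)
    ndays = values.shape[1]
    out = np.full((ndays, *target.shape), np.nan)
    out[:, ~mask] = fields.T
    return out


def grid_daily_temperature(stations: list[StationRecord], dem: Grid,
                           lapse: LapseModel = LapseModel(),
                           settings: InterpSettings = InterpSettings(),
                           dates: pd.DatetimeIndex | None = None) -> DailyStack:
    """Grid station records into a daily temperature stack on the DEM grid.

    Every station must cover every requested date (missing days are a
    hard error upstream in :func:`phenogrid.stations.read_station_table`).
    """
    if not stations:
        raise ValueError("no stations supplied")
    if dates is None:
        dates = stations[0].series.dates
    dates = pd.DatetimeIndex(dates)
    nsta = len(stations)
    sea = np.empty((nsta, len(dates)))
    lats = np.empty(nsta)
    lons = np.empty(nsta)
    for i, st in enumerate(stations):
        idx = st.series.dates.get_indexer(dates)
        if (idx < 0).any():
            missing = dates[np.nonzero(idx < 0)[0][0]]
            raise ValueError(
                f"station {st.id} does not cover {missing.date()}"
            )
        sea[i] = to_sea_level(st.series.values[idx], st.elev, lapse)
        lats[i], lons[i] = st.lat, st.lon
    fields = interpolate_days(lats, lons, sea, dem.geom, settings, dem.mask)
    elev = np.where(dem.mask, 0.0, dem.values)
    fields = fields - lapse.rate * elev / 100.0
    fields[:, dem.mask] = np.nan
    logger.info("gridded %d days from %d stations", len(dates), nsta)
    return DailyStack(dem.geom, dates, fields, dem.mask.copy())
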
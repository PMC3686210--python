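"""Convenience orchestration shared by the CLI and analysis scripts."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import DailyStack, Grid
from .stations import StationRecord
from .temperature import InterpSettings, LapseModel, grid_daily_temperature

logger = logging.getLogger(__name__)


def gridded_station_temperatures(stations: list[StationRecord], dem: Grid,
                                 years, lapse: LapseModel = LapseModel(),
                                 settings: InterpSettings = InterpSettings()
                                 ) -> dict[int, DailyStack]:
    """Interpolate all requested years in one batch, split per year.

    The station set is fixed across days, so the spline system is
    factored once for the whole span (years must be contiguous and fully
    covered by every station's series).
    """
    years = sorted(years)
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    stack = grid_daily_temperature(stations, dem, lapse, settings, dates)
    out: dict[int, DailyStack] = {}
    for year in years:
        sel = stack.dates.year == year
        out[year] = DailyStack(stack.geom, stack.dates[sel],
                               stack.values[sel], stack.mask)
    return out


def stack_climatology(stacks: dict[int, DailyStack]) -> np.ndarray:
    """Day-of-year mean over a set of yearly stacks (366, nrows, ncols)."""
    first = next(iter(stacks.values()))
    sums = np.zeros((366, *first.geom.shape))
    counts = np.zeros(366, int)
    for stack in stacks.values():
        doys = stack.dates.dayofyear.to_numpy()
        for i, doy in enumerate(doys):
            sums[doy - 1] += np.where(stack.mask, 0.0, stack.values[i])
            counts[doy - 1] += 1
    out = np.full_like(sums, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz][:, None, None]
    if counts[365] == 0:
        out[365] = out[364]
    out[:, first.mask] = np.nan
    return out
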
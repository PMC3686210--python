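"""Delta-method downscaling of coarse climate-model temperatures.

The delta field is a day-of-year climatology of the difference between the
fine station-derived baseline grids and the coarse climate-model baseline
regridded to the fine geometry.  Adding it to regridded future model days
transfers the model's anomalies onto the fine grid while preserving the
observed fine-scale (topographic) structure.  366 day-of-year slots are
kept; if the baseline contains no leap day, slot 366 copies slot 365.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import DailyStack, Grid, GridGeometry, regrid

logger = logging.getLogger(__name__)


@dataclass
class DeltaField:
    """Per-day-of-year (fine - regridded coarse) baseline differences."""

    geom: GridGeometry
    values: np.ndarray  # (366, nrows, ncols)
    mask: np.ndarray  # (nrows, ncols)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape != (366, *self.geom.shape):
            raise ValueError("delta field must have 366 day-of-year slots")
        if not np.isfinite(self.values[:, ~self.mask]).all():
            raise ValueError("delta field non-finite on unmasked cells")

    def for_doy(self, doy: int) -> np.ndarray:
        if not 1 <= doy <= 366:
            raise ValueError(f"day of year {doy} outside [1, 366]")
        return self.values[doy - 1]


def build_delta(fine_baseline: dict[int, DailyStack],
                coarse_baseline: dict[int, DailyStack],
                fine_geom: GridGeometry) -> DeltaField:
    """Climatological day-of-year mean of fine minus regridded coarse."""
    if sorted(fine_baseline) != sorted(coarse_baseline):
        raise ValueError(
            f"baseline year spans differ: fine {sorted(fine_baseline)} vs "
            f"coarse {sorted(coarse_baseline)}"
        )
    sums = np.zeros((366, *fine_geom.shape))
    counts = np.zeros(366, dtype=int)
    mask = None
    for year in sorted(fine_baseline):
        fine = fine_baseline[year]
        coarse = coarse_baseline[year]
        if not fine.geom.close_to(fine_geom):
            raise ValueError("fine baseline stack not on the target geometry")
        if not fine.dates.equals(coarse.dates):
            raise ValueError(f"fine/coarse dates differ in {year}")
        if mask is None:
            mask = fine.mask.copy()
        doys = fine.dates.dayofyear.to_numpy()
        for i, doy in enumerate(doys):
            cday = regrid(Grid(coarse.geom, coarse.values[i], coarse.mask),
                          fine_geom)
            diff = fine.values[i] - cday.values
            sums[doy - 1] += np.where(mask, 0.0, diff)
            counts[doy - 1] += 1
    assert mask is not None
    values = np.full((366, *fine_geom.shape), np.nan)
    nonzero = counts > 0
    values[nonzero] = sums[nonzero] / counts[nonzero][:, None, None]
    if counts[365] == 0:  # no leap day in the baseline: copy DOY 365
        values[365] = values[364]
    if (counts[:365] == 0).any():
        missing = np.nonzero(counts[:365] == 0)[0] + 1
        raise ValueError(f"baseline missing day-of-year slots: {missing.tolist()}")
    values[:, mask] = 0.0
    logger.info("built delta field over %d baseline years", len(fine_baseline))
    return DeltaField(fine_geom, values, mask)


def apply_delta(coarse_future: DailyStack, delta: DeltaField) -> DailyStack:
    """Downscale a coarse future stack: regrid then add the DOY delta."""
    doys = coarse_future.dates.dayofyear.to_numpy()
    out = np.empty((len(doys), *delta.geom.shape))
    for i, doy in enumerate(doys):
        cday = regrid(
            Grid(coarse_future.geom, coarse_future.values[i], coarse_future.mask),
            delta.geom,
        )
        out[i] = cday.values + delta.for_doy(int(doy))
    out[:, delta.mask] = np.nan
    return DailyStack(delta.geom, coarse_future.dates, out, delta.mask.copy())


def apply_delta_years(coarse_future: dict[int, DailyStack],
                      delta: DeltaField) -> dict[int, DailyStack]:
    return {year: apply_delta(stack, delta)
            for year, stack in sorted(coarse_future.items())}
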
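"""Geographic lat-lon grids and daily raster stacks.

All grids are cell-center registered, north-up, in geographic coordinates
(lat-lon), with the origin at the northwest cell center and the resolution
in arc-seconds.  Rows run north to south, columns west to east.  No
projected CRS is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARCSEC_PER_DEG = 3600.0


@dataclass(frozen=True)
class GridGeometry:
    """Shape and georeferencing of a lat-lon raster.

    Parameters
    ----------
    nrows, ncols:
        Grid shape.
    lat0, lon0:
        Coordinates (degrees) of the *northwest cell center*.
    res:
        Cell size in arc-seconds (square cells).
    """

    nrows: int
    ncols: int
    lat0: float
    lon0: float
    res: float

    def __post_init__(self) -> None:
        if self.res <= 0:
            raise ValueError(f"grid resolution must be positive, got {self.res}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def res_deg(self) -> float:
        return self.res / ARCSEC_PER_DEG

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def lats(self) -> np.ndarray:
        """Cell-center latitudes, north to south."""
        return self.lat0 - np.arange(self.nrows) * self.res_deg

    def lons(self) -> np.ndarray:
        """Cell-center longitudes, west to east."""
        return self.lon0 + np.arange(self.ncols) * self.res_deg

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.lats(), self.lons(), indexing="ij")

    def contains(self, lat: float, lon: float) -> bool:
        """Whether the point falls inside the grid's outer cell edges."""
        half = self.res_deg / 2
        return (
            self.lat0 + half >= lat > self.lat0 - self.nrows * self.res_deg + half
            and self.lon0 - half <= lon < self.lon0 + self.ncols * self.res_deg - half
        )

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/column of the cell containing a point."""
        if not self.contains(lat, lon):
            raise ValueError(f"point ({lat}, {lon}) outside grid extent")
        i = int(round((self.lat0 - lat) / self.res_deg))
        j = int(round((lon - self.lon0) / self.res_deg))
        return min(max(i, 0), self.nrows - 1), min(max(j, 0), self.ncols - 1)

    def refine(self, factor: int) -> "GridGeometry":
        """Geometry of this grid subdivided ``factor`` times per cell."""
        if factor < 1 or factor != int(factor):
            raise ValueError("refinement factor must be a positive integer")
        f = int(factor)
        fine_res = self.res / f
        half_shift = (self.res_deg - fine_res / ARCSEC_PER_DEG) / 2
        return GridGeometry(
            nrows=self.nrows * f,
            ncols=self.ncols * f,
            lat0=self.lat0 + half_shift,
            lon0=self.lon0 - half_shift,
            res=fine_res,
        )

    def coarsen(self, factor: int) -> "GridGeometry":
        """Geometry of this grid aggregated in ``factor`` x ``factor`` blocks."""
        f = int(factor)
        if f < 1 or factor != f:
            raise ValueError("coarsening factor must be a positive integer")
        if self.nrows % f or self.ncols % f:
            raise ValueError(
                f"grid shape {self.shape} not divisible by coarsening factor {f}"
            )
        coarse_res = self.res * f
        half_shift = (coarse_res / ARCSEC_PER_DEG - self.res_deg) / 2
        return GridGeometry(
            nrows=self.nrows // f,
            ncols=self.ncols // f,
            lat0=self.lat0 - half_shift,
            lon0=self.lon0 + half_shift,
            res=coarse_res,
        )

    def close_to(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.lat0 - other.lat0) <= tol
            and abs(self.lon0 - other.lon0) <= tol
            and abs(self.res - other.res) <= tol * ARCSEC_PER_DEG
        )


@dataclass
class Grid:
    """A lat-lon raster: values plus a nodata mask (True = nodata)."""

    geom: GridGeometry
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geom.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geom.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")

    @classmethod
    def full(cls, geom: GridGeometry, fill: float = np.nan) -> "Grid":
        return cls(geom, np.full(geom.shape, fill), np.zeros(geom.shape, bool))

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, self.mask)

    def copy(self) -> "Grid":
        return Grid(self.geom, self.values.copy(), self.mask.copy())


@dataclass
class DailyStack:
    """A stack of daily grids sharing one geometry and nodata mask."""

    geom: GridGeometry
    dates: pd.DatetimeIndex
    values: np.ndarray  # (ndays, nrows, ncols)
    mask: np.ndarray  # (nrows, ncols), True = nodata

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.dates), *self.geom.shape):
            raise ValueError(
                f"stack shape {self.values.shape} inconsistent with "
                f"{len(self.dates)} dates and geometry {self.geom.shape}"
            )
        if self.mask.shape != self.geom.shape:
            raise ValueError("mask shape must match geometry")
        if len(self.dates) > 1:
            steps = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (steps == np.timedelta64(1, "D")).all():
                raise ValueError("stack dates must be contiguous daily")

    def day(self, date) -> Grid:
        date = pd.Timestamp(date)
        loc = self.dates.get_loc(date)
        return Grid(self.geom, self.values[loc].copy(), self.mask.copy())


def regrid(grid: Grid, target: GridGeometry) -> Grid:
    """Resample between nested resolutions.

    Refinement (target finer) assigns each fine cell its containing coarse
    cell's value (nearest neighbour); coarsening takes the mean over the
    unmasked cells of each block, masking blocks that are fully masked.
    The target must be an exact integer refinement or coarsening of the
    source geometry.
    """
    src = grid.geom
    if target.close_to(src):
        return grid.copy()
    if target.res < src.res:
        ratio = src.res / target.res
        f = int(round(ratio))
        if abs(ratio - f) > 1e-9 or not src.refine(f).close_to(target):
            raise ValueError(
                "target geometry is not an integer refinement of the source"
            )
        values = np.repeat(np.repeat(grid.values, f, axis=0), f, axis=1)
        mask = np.repeat(np.repeat(grid.mask, f, axis=0), f, axis=1)
        return Grid(target, values, mask)
    ratio = target.res / src.res
    f = int(round(ratio))
    if abs(ratio - f) > 1e-9 or not src.coarsen(f).close_to(target):
        raise ValueError("target geometry is not an integer coarsening of the source")
    nr, nc = target.shape
    vals = np.where(grid.mask, 0.0, grid.values).reshape(nr, f, nc, f)
    valid = (~grid.mask).reshape(nr, f, nc, f)
    counts = valid.sum(axis=(1, 3))
    sums = (vals * valid).sum(axis=(1, 3))
    out_mask = counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_mask, np.nan, sums / np.maximum(counts, 1))
    return Grid(target, out, out_mask)


def regrid_stack(stack: DailyStack, target: GridGeometry) -> DailyStack:
    """Apply :func:`regrid` to every day of a stack."""
    days = [regrid(Grid(stack.geom, stack.values[i], stack.mask), target)
            for i in range(len(stack.dates))]
    values = np.stack([g.values for g in days])
    return DailyStack(target, stack.dates, values, days[0].mask)
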
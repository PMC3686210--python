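"""NetCDF readers and writers for grids, daily stacks, and onset maps.

Everything is geographic (lat-lon); files carrying a projected CRS are
rejected with instructions to reproject first.  Round-trips preserve
values, mask, origin, and resolution exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import ARCSEC_PER_DEG, DailyStack, Grid, GridGeometry

_ENGINE = "scipy"  # NetCDF3; deterministic byte-for-byte output
_CRS = "geographic lat-lon (EPSG:4326)"

ONSET_NODATA = -1


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix != ".nc":
        raise ValueError(
            f"unsupported raster format {path.suffix!r}: only NetCDF (.nc) "
            "is supported; convert other formats to NetCDF first"
        )
    return path


def _check_crs(attrs: dict) -> None:
    crs = str(attrs.get("crs", _CRS))
    if "EPSG:4326" not in crs and "lat-lon" not in crs and "latlon" not in crs:
        raise ValueError(
            f"raster has projected CRS {crs!r}: reproject to geographic "
            "lat-lon (EPSG:4326) before use"
        )


def _geom_from_ds(ds: xr.Dataset) -> GridGeometry:
    _check_crs(ds.attrs)
    return GridGeometry(
        nrows=ds.sizes["lat"],
        ncols=ds.sizes["lon"],
        lat0=float(ds.attrs["lat0"]),
        lon0=float(ds.attrs["lon0"]),
        res=float(ds.attrs["res_arcsec"]),
    )


def _geom_attrs(geom: GridGeometry) -> dict:
    return {
        "crs": _CRS,
        "lat0": geom.lat0,
        "lon0": geom.lon0,
        "res_arcsec": geom.res,
        "registration": "cell-center, origin at northwest cell",
    }


def _coords(geom: GridGeometry) -> dict:
    return {"lat": geom.lats(), "lon": geom.lons()}


def write_raster(path: str | Path, grid: Grid, var: str = "values") -> None:
    """Write a single 2-D grid to NetCDF (values + nodata mask)."""
    path = _check_path(path)
    ds = xr.Dataset(
        {
            var: (("lat", "lon"), grid.values),
            "mask": (("lat", "lon"), grid.mask.astype(np.int8)),
        },
        coords=_coords(grid.geom),
        attrs=_geom_attrs(grid.geom),
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_raster(path: str | Path, var: str = "values") -> Grid:
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        geom = _geom_from_ds(ds)
        values = ds[var].values.astype(float)
        mask = ds["mask"].values.astype(bool)
    return Grid(geom, values, mask)


def write_stack(path: str | Path, stack: DailyStack, var: str = "tmean") -> None:
    """Write a daily grid stack (time, lat, lon) to NetCDF."""
    path = _check_path(path)
    ds = xr.Dataset(
        {
            var: (("time", "lat", "lon"), stack.values),
            "mask": (("lat", "lon"), stack.mask.astype(np.int8)),
        },
        coords={"time": stack.dates, **_coords(stack.geom)},
        attrs=_geom_attrs(stack.geom),
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_stack(path: str | Path, var: str = "tmean") -> DailyStack:
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        geom = _geom_from_ds(ds)
        dates = pd.DatetimeIndex(ds["time"].values)
        values = ds[var].values.astype(float)
        mask = ds["mask"].values.astype(bool)
    return DailyStack(geom, dates, values, mask)


def write_fields(path: str | Path, geom: GridGeometry,
                 fields: dict[str, np.ndarray], attrs: dict | None = None
                 ) -> None:
    """Write a set of co-registered 2-D fields (e.g. calibrated params)."""
    path = _check_path(path)
    ds = xr.Dataset(
        {name: (("lat", "lon"), np.asarray(arr)) for name, arr in fields.items()},
        coords=_coords(geom),
        attrs={**_geom_attrs(geom), **(attrs or {})},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_fields(path: str | Path) -> tuple[GridGeometry, dict[str, np.ndarray], dict]:
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(f"field file not found: {path}")
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        geom = _geom_from_ds(ds)
        fields = {name: ds[name].values for name in ds.data_vars}
        attrs = dict(ds.attrs)
    return geom, fields, attrs


def write_delta(path: str | Path, geom: GridGeometry, values: np.ndarray,
                mask: np.ndarray) -> None:
    """Write a 366-layer day-of-year delta field."""
    path = _check_path(path)
    ds = xr.Dataset(
        {
            "delta": (("doy", "lat", "lon"), values),
            "mask": (("lat", "lon"), mask.astype(np.int8)),
        },
        coords={"doy": np.arange(1, 367), **_coords(geom)},
        attrs=_geom_attrs(geom),
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_delta(path: str | Path) -> tuple[GridGeometry, np.ndarray, np.ndarray]:
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(f"delta field not found: {path}")
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        geom = _geom_from_ds(ds)
        values = ds["delta"].values.astype(float)
        mask = ds["mask"].values.astype(bool)
    return geom, values, mask


def write_grvi(path: str | Path, geom: GridGeometry, starts: np.ndarray,
               values: np.ndarray, year: int) -> None:
    """Write an 8-day-composite GRVI stack for one year."""
    path = _check_path(path)
    ds = xr.Dataset(
        {"grvi": (("composite", "lat", "lon"), values)},
        coords={"composite": np.asarray(starts, np.int32), **_coords(geom)},
        attrs={**_geom_attrs(geom), "year": year,
               "composite_coord": "start day of year of each composite"},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_grvi(path: str | Path):
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(f"GRVI stack not found: {path}")
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        geom = _geom_from_ds(ds)
        starts = ds["composite"].values.astype(int)
        values = ds["grvi"].values.astype(float)
        year = int(ds.attrs["year"])
    return geom, starts, values, year


def write_onset_raster(path: str | Path, geom: GridGeometry, doy: np.ndarray,
                       year: int) -> None:
    """Write an integer onset-DOY raster; nodata cells hold -1."""
    path = _check_path(path)
    doy = np.asarray(doy)
    ds = xr.Dataset(
        {"onset_doy": (("lat", "lon"), doy.astype(np.int32))},
        coords=_coords(geom),
        attrs={**_geom_attrs(geom), "year": year, "nodata": ONSET_NODATA},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_onset_raster(path: str | Path) -> tuple[GridGeometry, np.ndarray, int]:
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(f"onset raster not found: {path}")
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        geom = _geom_from_ds(ds)
        doy = ds["onset_doy"].values.astype(np.int32)
        year = int(ds.attrs["year"])
    return geom, doy, year
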
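"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the three data sources the real
analysis rests on: a quasi-uniform station network sampling a smooth
lapse-consistent temperature field, a coarse biased climate model with
prescribed decadal warming, and 8-day vegetation-index composites whose
green-up crossing encodes onset dates produced by a known SW or PC
process.  Everything is deterministic under the configured seed.

Weather is defined as a function of (year, day-of-year): a static spatial
field (latitudinal gradient, a gentle smooth anomaly, and the elevation
lapse) plus a seasonal cycle indexed by DOY and a per-day regional
anomaly drawn per year.  Future years reuse the anomaly stream of an
analog baseline year plus the decade's warming offset, so the delta
method has a well-defined target.  Leap years simply carry one extra
DOY sample, which keeps degree-day accumulations identical functions of
DOY across years — the property that makes noise-free round-trip
calibration exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import DailyStack, Grid, GridGeometry, regrid_stack
from .onset import NOT_DETECTED, OnsetMap
from .stations import DailySeries, StationRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic world (defaults = study conditions)."""

    # Fine (phenology) grid
    nrows: int = 24
    ncols: int = 24
    res_arcsec: float = 450.0  # 3-degree domain at 24 cells
    lat0: float = 44.0
    lon0: float = 138.0
    coarse_factor: int = 4  # climate-model grid is 4x coarser

    # Terrain
    max_elev: float = 1500.0
    n_ridges: int = 4
    flat_dem: bool = False
    sea_corner: bool = True  # mask an ocean corner in the southeast

    # Station network (quasi-uniform, like a real ~20-km mesonet)
    n_stations: int = 25

    # Climate
    mean_temp: float = 9.0  # degC annual mean at sea level, domain centre
    lat_gradient: float = 1.0  # degC cooler per degree northward
    lon_gradient: float = 0.2  # degC per degree eastward
    bump_amp: float = 0.5  # degC, static smooth regional anomaly
    bump_width_deg: float = 1.0
    seasonal_amp: float = 11.0  # degC, half range of the annual cycle
    coldest_doy: int = 15
    daily_sd: float = 2.0  # degC, day-to-day regional anomaly
    tilt_sd: float = 0.15  # degC per degree, daily random gradient
    lapse_rate: float = 0.6  # K per 100 m

    # Phenology truth (per-pixel fields tied to local annual-mean temp)
    model: str = "sw"  # family generating the truth onsets: "sw" | "pc"
    gddc_base: float = 200.0
    gddc_per_degc: float = 25.0
    gddc_lim: tuple[float, float] = (120.0, 600.0)
    a_base: float = -20.0
    a_per_degc: float = 18.0
    a_lim: tuple[float, float] = (-100.0, 200.0)
    ref_temp: float = 5.0
    k: float = 0.0
    start_doy: int = 1
    kprime: float = 5.0
    b: float = 1084.0
    c: float = -0.00904
    chill_start: tuple[int, int] = (11, 1)

    # Coarse climate model emulation
    gcm_bias: float = 1.5  # degC, amplitude of the smooth additive bias
    warming: dict = field(
        default_factory=lambda: {"2030s": 1.5, "2090s": 3.2}
    )
    warming_gradient: float = 0.0  # extra degC per degree northward

    # Vegetation index
    grvi_low: float = -0.1
    grvi_high: float = 0.6
    grvi_width: float = 5.0  # days, logistic green-up transition
    grvi_noise_sd: float = 0.01
    composite_period: int = 8
    first_composite_doy: int = 1

    # Year spans
    calib_years: tuple[int, int] = (2001, 2009)
    delta_years: tuple[int, int] = (1994, 2003)
    decades: dict = field(
        default_factory=lambda: {"2030s": (2030, 2039), "2090s": (2090, 2099)}
    )

    seed: int = 0

    def __post_init__(self) -> None:
        if self.coarse_factor < 2:
            raise ValueError("coarsening factor must be an integer >= 2")
        for name in ("daily_sd", "tilt_sd", "grvi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.model not in ("sw", "pc"):
            raise ValueError("truth model must be 'sw' or 'pc'")
        if self.nrows % self.coarse_factor or self.ncols % self.coarse_factor:
            raise ValueError("grid shape must be divisible by the coarse factor")

    def noise_free(self) -> "SynthConfig":
        """Identical world with all stochastic day/pixel noise switched off."""
        return replace(self, daily_sd=0.0, tilt_sd=0.0, grvi_noise_sd=0.0)

    @classmethod
    def tiny(cls, **kw) -> "SynthConfig":
        """A minimal preset for smoke tests: 8x8 grid, 3 years, 1 decade."""
        defaults = dict(
            nrows=8, ncols=8, res_arcsec=1350.0, n_stations=9,
            coarse_factor=2, n_ridges=2,
            calib_years=(2001, 2003), delta_years=(2001, 2002),
            decades={"2030s": (2030, 2031)}, warming={"2030s": 1.5},
        )
        defaults.update(kw)
        return cls(**defaults)

    @property
    def fine_geom(self) -> GridGeometry:
        return GridGeometry(self.nrows, self.ncols, self.lat0, self.lon0,
                            self.res_arcsec)

    @property
    def coarse_geom(self) -> GridGeometry:
        return self.fine_geom.coarsen(self.coarse_factor)

    @property
    def observed_years(self) -> list[int]:
        first = min(self.delta_years[0], self.calib_years[0] - 1)
        last = max(self.delta_years[1], self.calib_years[1])
        return list(range(first, last + 1))

    def decade_years(self, label: str) -> list[int]:
        """Years of a future decade including the pre-year for chilling."""
        d0, d1 = self.decades[label]
        return list(range(d0 - 1, d1 + 1))

    def analog_year(self, year: int) -> int:
        """Baseline year whose weather a future year reuses."""
        for label, (d0, d1) in self.decades.items():
            if d0 - 1 <= year <= d1:
                return self.delta_years[0] + (year - d0)
        return year

    def warming_offset(self, year: int) -> float | None:
        """Decadal warming (degC) applied to a future year, else None."""
        for label, (d0, d1) in self.decades.items():
            if d0 - 1 <= year <= d1:
                return float(self.warming[label])
        return None


def _domain_center(cfg: SynthConfig) -> tuple[float, float]:
    geom = cfg.fine_geom
    return (float(geom.lats().mean()), float(geom.lons().mean()))


def make_dem(cfg: SynthConfig) -> Grid:
    """Smooth ridged terrain with an optional masked sea corner."""
    geom = cfg.fine_geom
    lat, lon = geom.mesh()
    rng = np.random.default_rng([cfg.seed, 11])
    elev = np.zeros(geom.shape)
    if not cfg.flat_dem:
        lat_span = geom.nrows * geom.res_deg
        lon_span = geom.ncols * geom.res_deg
        for _ in range(cfg.n_ridges):
            clat = geom.lat0 - rng.uniform(0.15, 0.85) * lat_span
            clon = geom.lon0 + rng.uniform(0.15, 0.85) * lon_span
            width = rng.uniform(0.25, 0.6)
            height = rng.uniform(0.4, 1.0)
            elev += height * np.exp(
                -((lat - clat) ** 2 + (lon - clon) ** 2) / (2 * width**2)
            )
        if elev.max() > 0:
            elev *= cfg.max_elev / elev.max()
    mask = np.zeros(geom.shape, bool)
    if cfg.sea_corner:
        # ocean in the southeast: beyond a diagonal through the corner
        lat_min = geom.lats()[-1]
        lon_max = geom.lons()[-1]
        span = geom.nrows * geom.res_deg
        d = (lat - lat_min) / span + (lon_max - lon) / span
        mask = d < 0.35
        elev = np.where(mask, np.nan, elev)
    return Grid(geom, elev, mask)


def static_sea_level_field(cfg: SynthConfig) -> np.ndarray:
    """Time-invariant annual-mean temperature at sea level (degC)."""
    geom = cfg.fine_geom
    lat, lon = geom.mesh()
    clat, clon = _domain_center(cfg)
    blat = clat - 0.3
    blon = clon + 0.3
    bump = cfg.bump_amp * np.exp(
        -((lat - blat) ** 2 + (lon - blon) ** 2) / (2 * cfg.bump_width_deg**2)
    )
    return (cfg.mean_temp - cfg.lat_gradient * (lat - clat)
            + cfg.lon_gradient * (lon - clon) + bump)


def annual_mean_temperature(cfg: SynthConfig, dem: Grid) -> np.ndarray:
    """Deterministic annual-mean temperature at each cell (degC)."""
    elev = np.where(dem.mask, 0.0, dem.values)
    out = static_sea_level_field(cfg) - cfg.lapse_rate * elev / 100.0
    return np.where(dem.mask, np.nan, out)


def _seasonal(cfg: SynthConfig, doys: np.ndarray) -> np.ndarray:
    return -cfg.seasonal_amp * np.cos(
        2 * math.pi * (doys - cfg.coldest_doy) / 365.0
    )


def _daily_anomalies(cfg: SynthConfig, analog: int) -> tuple[np.ndarray, ...]:
    """Per-DOY regional anomaly and gradient tilts for one weather year."""
    rng = np.random.default_rng([cfg.seed, 101, analog])
    a0 = rng.normal(0.0, cfg.daily_sd, 366)
    tlat = rng.normal(0.0, cfg.tilt_sd, 366)
    tlon = rng.normal(0.0, cfg.tilt_sd, 366)
    return a0, tlat, tlon


def make_climate_year(cfg: SynthConfig, dem: Grid, year: int) -> DailyStack:
    """Fine-grid daily truth temperatures for one calendar year."""
    geom = cfg.fine_geom
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doys = dates.dayofyear.to_numpy()
    # Weather is indexed by DOY in spring/summer, and by days-until-year-end
    # in the Nov-Dec chilling window (leap autumns drop back by one), so
    # degree-day and chilling-day accumulations are identical functions of
    # DOY across leap and non-leap years -- the convention of a fixed-length
    # model calendar, and what makes noise-free round trips exact.
    ndays = len(dates)
    doy_key = np.where(dates.month.to_numpy() >= 11, doys - (ndays - 365), doys)
    lat, lon = geom.mesh()
    clat, clon = _domain_center(cfg)
    elev = np.where(dem.mask, 0.0, dem.values)
    static = static_sea_level_field(cfg) - cfg.lapse_rate * elev / 100.0
    a0, tlat, tlon = _daily_anomalies(cfg, cfg.analog_year(year))
    values = (
        static[None]
        + _seasonal(cfg, doy_key)[:, None, None]
        + a0[doy_key - 1][:, None, None]
        + tlat[doy_key - 1][:, None, None] * (lat - clat)[None]
        + tlon[doy_key - 1][:, None, None] * (lon - clon)[None]
    )
    offset = cfg.warming_offset(year)
    if offset is not None:
        values = values + offset + cfg.warming_gradient * (lat - clat)[None]
    values[:, dem.mask] = np.nan
    return DailyStack(geom, dates, values, dem.mask.copy())


def make_climate(cfg: SynthConfig, dem: Grid,
                 years=None) -> dict[int, DailyStack]:
    """Fine-grid truth stacks for the observed years (or any year list)."""
    if years is None:
        years = cfg.observed_years
    return {y: make_climate_year(cfg, dem, y) for y in years}


def station_cells(cfg: SynthConfig, dem: Grid) -> list[tuple[int, int]]:
    """Quasi-uniform (jittered-grid) station cells, land only, distinct."""
    rng = np.random.default_rng([cfg.seed, 21])
    k = max(int(round(math.sqrt(cfg.n_stations))), 1)
    cells: list[tuple[int, int]] = []
    taken = set()

    def nearest_free_land(r0: int, c0: int) -> tuple[int, int] | None:
        for radius in range(max(cfg.nrows, cfg.ncols)):
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    r, c = r0 + dr, c0 + dc
                    if (0 <= r < cfg.nrows and 0 <= c < cfg.ncols
                            and not dem.mask[r, c] and (r, c) not in taken):
                        return r, c
        return None

    for i in range(k):
        for j in range(k):
            if len(cells) >= cfg.n_stations:
                break
            r0 = int(round((i + 0.5) * cfg.nrows / k - 0.5))
            c0 = int(round((j + 0.5) * cfg.ncols / k - 0.5))
            r0 = int(np.clip(r0 + rng.integers(-1, 2), 0, cfg.nrows - 1))
            c0 = int(np.clip(c0 + rng.integers(-1, 2), 0, cfg.ncols - 1))
            found = nearest_free_land(r0, c0)
            if found:
                taken.add(found)
                cells.append(found)
    while len(cells) < cfg.n_stations:
        r = int(rng.integers(0, cfg.nrows))
        c = int(rng.integers(0, cfg.ncols))
        found = nearest_free_land(r, c)
        if found is None:
            raise ValueError("not enough land cells for the station network")
        taken.add(found)
        cells.append(found)
    return cells


def make_stations(cfg: SynthConfig, dem: Grid,
                  truth: dict[int, DailyStack]) -> list[StationRecord]:
    """Station records sampling exact truth values at fixed land cells."""
    cells = station_cells(cfg, dem)
    years = sorted(set(cfg.observed_years) & set(truth))
    dates = pd.DatetimeIndex(
        np.concatenate([truth[y].dates.values for y in years])
    )
    geom = dem.geom
    lats, lons = geom.lats(), geom.lons()
    records = []
    for n, (r, c) in enumerate(cells):
        values = np.concatenate([truth[y].values[:, r, c] for y in years])
        records.append(
            StationRecord(
                id=f"S{n:03d}",
                lat=float(lats[r]),
                lon=float(lons[c]),
                elev=float(dem.values[r, c]),
                series=DailySeries(dates, values),
            )
        )
    return records


def _gcm_bias_field(cfg: SynthConfig) -> np.ndarray:
    """Smooth additive bias of the emulated climate model (coarse grid)."""
    geom = cfg.coarse_geom
    lat, lon = geom.mesh()
    clat, clon = _domain_center(cfg)
    lat_span = cfg.nrows * cfg.fine_geom.res_deg
    return cfg.gcm_bias * (
        0.6 + 0.8 * (lat - clat) / lat_span - 0.4 * (lon - clon) / lat_span
    )


def make_gcm(cfg: SynthConfig, truth: dict[int, DailyStack],
             years=None) -> dict[int, DailyStack]:
    """Coarse biased climate-model stacks from fine truth stacks.

    Each coarse day is the block mean of the fine truth plus a static
    smooth bias; future years already carry their warming offset in the
    truth, so the coarse product inherits it.
    """
    if years is None:
        years = sorted(truth)
    bias = _gcm_bias_field(cfg)
    out = {}
    for y in years:
        coarse = regrid_stack(truth[y], cfg.coarse_geom)
        values = coarse.values + bias[None]
        values[:, coarse.mask] = np.nan
        out[y] = DailyStack(cfg.coarse_geom, coarse.dates, values, coarse.mask)
    return out


def truth_parameter_field(cfg: SynthConfig, dem: Grid) -> np.ndarray:
    """The generating per-pixel parameter: gddc* (SW) or a* (PC).

    Both increase with the local annual-mean temperature, mirroring the
    observed acclimation of the warmth requirement to local climate.
    """
    t_ann = annual_mean_temperature(cfg, dem)
    if cfg.model == "sw":
        raw = cfg.gddc_base + cfg.gddc_per_degc * (t_ann - cfg.ref_temp)
        lo, hi = cfg.gddc_lim
    else:
        raw = cfg.a_base + cfg.a_per_degc * (t_ann - cfg.ref_temp)
        lo, hi = cfg.a_lim
    return np.where(dem.mask, np.nan, np.clip(raw, lo, hi))


def scan_onset_map(cfg: SynthConfig, dates: pd.DatetimeIndex,
                   values: np.ndarray, param: np.ndarray) -> np.ndarray:
    """Exhaustive day-by-day scan for the first threshold crossing.

    Walks the year one day at a time, accumulating GDD (and NCD for the
    PC family) and recording the first DOY whose GDD reaches the
    critical sum.  Serves as the generator's ground truth and as an
    independent oracle for the vectorised predictors.
    """
    year = int(dates[-1].year)
    shape = values.shape[1:]
    gdd = np.zeros(shape)
    ncd = np.zeros(shape)
    onset = np.full(shape, NOT_DETECTED, dtype=np.int32)
    chill_begun = pd.Timestamp(year - 1, *cfg.chill_start)
    for i, ts in enumerate(dates):
        day = values[i]
        if ts >= chill_begun:
            ncd = ncd + (day < cfg.kprime)
        if ts.year == year and ts.dayofyear >= cfg.start_doy:
            gdd = gdd + np.clip(day - cfg.k, 0.0, None)
            if cfg.model == "sw":
                threshold = param
            else:
                threshold = param + cfg.b * np.exp(cfg.c * ncd)
            hit = (onset == NOT_DETECTED) & (gdd >= threshold)
            onset[hit] = ts.dayofyear
    return onset


def _composite_starts(cfg: SynthConfig, ndays: int) -> np.ndarray:
    return np.arange(cfg.first_composite_doy, ndays + 1, cfg.composite_period)


def make_onsets(cfg: SynthConfig, dem: Grid, truth: dict[int, DailyStack]):
    """True onset maps plus GRVI composite stacks for the calibration years.

    Returns ``(truth_onsets, grvi)`` where ``grvi[year]`` is a pair
    ``(composite_start_doys, values)``; pixels whose truth model never
    fires show a flat low GRVI trajectory.
    """
    from .models import assemble_model_year  # local import avoids a cycle

    param = truth_parameter_field(cfg, dem)
    y0, y1 = cfg.calib_years
    truth_onsets: dict[int, OnsetMap] = {}
    grvi: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for year in range(y0, y1 + 1):
        dates, values = assemble_model_year(
            truth, year, include_prior_autumn=(cfg.model == "pc"),
            chill_start=cfg.chill_start,
        )
        onset = scan_onset_map(cfg, pd.DatetimeIndex(dates), values, param)
        onset[dem.mask] = NOT_DETECTED
        truth_onsets[year] = OnsetMap(year, dem.geom, onset)
        ndays = int(pd.Timestamp(year, 12, 31).dayofyear)
        starts = _composite_starts(cfg, ndays)
        low, high, width = cfg.grvi_low, cfg.grvi_high, cfg.grvi_width
        d = starts[:, None, None].astype(float)
        o = onset[None].astype(float)
        if width > 0:
            curve = low + (high - low) / (1.0 + np.exp(-(d - o) / width))
        else:
            curve = np.where(d >= o, high, low)
        curve = np.where(onset[None] == NOT_DETECTED, low, curve)
        if cfg.grvi_noise_sd > 0:
            rng = np.random.default_rng([cfg.seed, 303, year])
            curve = curve + rng.normal(0.0, cfg.grvi_noise_sd, curve.shape)
        curve = np.clip(curve, -1.0, 1.0)
        curve[:, dem.mask] = np.nan
        grvi[year] = (starts, curve)
    return truth_onsets, grvi


@dataclass
class SynthData:
    """Everything the pipeline needs, with ground truth retained."""

    cfg: SynthConfig
    dem: Grid
    truth_fine: dict[int, DailyStack]  # observed years
    truth_future: dict[str, dict[int, DailyStack]]  # decade -> year -> stack
    stations: list[StationRecord]
    coarse_baseline: dict[int, DailyStack]
    coarse_future: dict[str, dict[int, DailyStack]]
    truth_onsets: dict[int, OnsetMap]
    grvi: dict[int, tuple[np.ndarray, np.ndarray]]
    truth_param: np.ndarray  # gddc* or a* field


def generate(cfg: SynthConfig) -> SynthData:
    """Produce the complete synthetic fixture for one configuration."""
    dem = make_dem(cfg)
    truth_fine = make_climate(cfg, dem)
    truth_future = {
        label: make_climate(cfg, dem, cfg.decade_years(label))
        for label in sorted(cfg.decades)
    }
    stations = make_stations(cfg, dem, truth_fine)
    d0, d1 = cfg.delta_years
    coarse_baseline = make_gcm(
        cfg, {y: truth_fine[y] for y in range(d0, d1 + 1)}
    )
    coarse_future = {
        label: make_gcm(cfg, truth_future[label])
        for label in sorted(cfg.decades)
    }
    truth_onsets, grvi = make_onsets(cfg, dem, truth_fine)
    logger.info(
        "synthetic world: %dx%d grid, %d stations, %d observed years, "
        "%d future decades",
        cfg.nrows, cfg.ncols, len(stations), len(truth_fine),
        len(cfg.decades),
    )
    return SynthData(
        cfg=cfg, dem=dem, truth_fine=truth_fine, truth_future=truth_future,
        stations=stations, coarse_baseline=coarse_baseline,
        coarse_future=coarse_future, truth_onsets=truth_onsets, grvi=grvi,
        truth_param=truth_parameter_field(cfg, dem),
    )
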
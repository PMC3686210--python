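"""Pipeline configuration with the published model constants as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline.

    Defaults are the published calibration for cool-temperate deciduous
    forest in Japan: a 0.6 K / 100 m lapse rate, GDD base temperature
    k = 0 degC accumulated from 1 January, chilling ceiling k' = 5 degC
    counted from 1 November, exponential chilling-response constants
    b = 1084 and c = -0.00904 degC-day, green-up threshold GRVI > 0.05
    detected no later than DOY 200.
    """

    # Study extent (degrees): lat_min, lat_max, lon_min, lon_max
    extent: tuple[float, float, float, float] = (29.970833, 46.075, 129.029167, 147.975)
    # Grid resolutions in arc-seconds
    temp_res_arcsec: float = 30.0
    pheno_res_arcsec: float = 15.0

    # Lapse-rate reduction to sea level
    lapse_rate: float = 0.6  # K per 100 m

    # Spring-warming model
    k: float = 0.0  # degC, base temperature for GDD
    gdd_start_doy: int = 1  # 1 January

    # Parallel-chill model
    kprime: float = 5.0  # degC, ceiling temperature for a chilling day
    chill_start_month: int = 11
    chill_start_day: int = 1
    b: float = 1084.0  # degC-day
    c: float = -0.00904  # per chilling day

    # Green-up detection
    grvi_threshold: float = 0.05
    onset_cutoff_doy: int = 200

    # Interpolation
    tension: float = 1e-10  # spline smoothing; ~0 = near-interpolating
    min_stations: int = 4

    # Year spans
    calib_years: tuple[int, int] = (2001, 2009)
    delta_years: tuple[int, int] = (1994, 2003)
    decades: dict = field(
        default_factory=lambda: {"2030s": (2030, 2039), "2090s": (2090, 2099)}
    )

    # Validation / scenario reporting
    rmse_report_threshold: float = 8.0  # days
    min_valid_years_per_decade: int = 5
    area_weighting: bool = False  # unweighted regional mean/median

    seed: int = 0

    def __post_init__(self) -> None:
        if self.lapse_rate < 0:
            raise ValueError("lapse rate must be >= 0")
        if not (-1 < self.grvi_threshold < 1):
            raise ValueError("GRVI threshold must lie in (-1, 1)")
        if not (1 <= self.onset_cutoff_doy <= 366):
            raise ValueError("onset cutoff DOY must lie in [1, 366]")
        if self.tension <= 0:
            raise ValueError("tension must be positive")
        if self.min_stations < 3:
            raise ValueError("min_stations must be >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("extent", "calib_years", "delta_years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "decades" in raw:
            raw["decades"] = {k: tuple(v) for k, v in raw["decades"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["extent"] = list(self.extent)
        data["calib_years"] = list(self.calib_years)
        data["delta_years"] = list(self.delta_years)
        data["decades"] = {k: list(v) for k, v in self.decades.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
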
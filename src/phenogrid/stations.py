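"""Station records: daily mean-temperature series at point locations."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DailySeries:
    """A contiguous daily series of mean air temperature (degC).

    Dates must be strictly increasing with a step of exactly one day and
    values must be finite: gaps are rejected here, never filled.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must have equal length")
        if len(self.dates) == 0:
            raise ValueError("empty series")
        steps = np.diff(self.dates.values).astype("timedelta64[D]")
        if (steps <= np.timedelta64(0, "D")).any():
            raise ValueError("dates must be strictly increasing")
        bad = np.nonzero(steps != np.timedelta64(1, "D"))[0]
        if bad.size:
            missing = self.dates[bad[0]] + pd.Timedelta(days=1)
            raise ValueError(f"gap in daily series: missing {missing.date()}")
        if not np.isfinite(self.values).all():
            raise ValueError("series contains non-finite temperatures")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class StationRecord:
    """One weather station: location, elevation, and its daily series."""

    id: str
    lat: float
    lon: float
    elev: float
    series: DailySeries

    def __post_init__(self) -> None:
        if self.elev < -100:
            raise ValueError(f"station {self.id}: elevation {self.elev} m < -100 m")


STATION_COLUMNS = ["id", "lat", "lon", "elev", "date", "tmean"]


def read_station_table(path: str | Path) -> list[StationRecord]:
    """Read a station CSV (columns id,lat,lon,elev,date,tmean; ISO dates).

    Rows may arrive in any order; each station's series is sorted and must
    then be contiguous daily.  Duplicate (station, date) pairs and gaps are
    hard errors naming the offending station and date.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station table missing columns: {sorted(missing)}")
    records: list[StationRecord] = []
    for sid, g in df.groupby("id", sort=True):
        g = g.sort_values("date")
        dup = g["date"].duplicated()
        if dup.any():
            d = g.loc[dup, "date"].iloc[0]
            raise ValueError(f"duplicate record for station {sid} on {d.date()}")
        for col in ("lat", "lon", "elev"):
            if g[col].nunique() > 1:
                raise ValueError(f"station {sid} has inconsistent {col} values")
        series = DailySeries(pd.DatetimeIndex(g["date"]), g["tmean"].to_numpy())
        records.append(
            StationRecord(
                id=str(sid),
                lat=float(g["lat"].iloc[0]),
                lon=float(g["lon"].iloc[0]),
                elev=float(g["elev"].iloc[0]),
                series=series,
            )
        )
    logger.debug("read %d stations from %s", len(records), path)
    return records


def write_station_table(path: str | Path, stations: list[StationRecord]) -> None:
    frames = []
    for st in stations:
        frames.append(
            pd.DataFrame(
                {
                    "id": st.id,
                    "lat": st.lat,
                    "lon": st.lon,
                    "elev": st.elev,
                    "date": st.series.dates.strftime("%Y-%m-%d"),
                    "tmean": st.series.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
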
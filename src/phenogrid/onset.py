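"""Leaf-onset detection from GRVI composite time series.

Onset is the start day of the first 8-day composite whose green-red
vegetation index strictly exceeds the threshold (default 0.05), provided
that composite starts no later than the cutoff (default DOY 200).  Pixels
that never satisfy the rule carry no onset for the year, which in the
source imagery happens mostly over evergreen forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import GridGeometry

logger = logging.getLogger(__name__)

NOT_DETECTED = -1


def grvi(green, red):
    """Green-red vegetation index (green - red) / (green + red)."""
    green = np.asarray(green, float)
    red = np.asarray(red, float)
    if (green < 0).any() or (green > 1).any() or (red < 0).any() or (red > 1).any():
        raise ValueError("reflectances must lie in [0, 1]")
    total = green + red
    if (total == 0).any():
        raise ValueError("green + red reflectance is zero")
    out = (green - red) / total
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DetectionRule:
    threshold: float = 0.05
    cutoff_doy: int = 200

    def __post_init__(self) -> None:
        if not -1 < self.threshold < 1:
            raise ValueError("threshold must lie in (-1, 1)")
        if not 1 <= self.cutoff_doy <= 366:
            raise ValueError("cutoff DOY must lie in [1, 366]")


@dataclass
class GRVISeries:
    """GRVI values of one pixel at 8-day composite starts within one year."""

    year: int
    composite_start_doys: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.composite_start_doys = np.asarray(self.composite_start_doys, int)
        self.values = np.asarray(self.values, float)
        if len(self.composite_start_doys) != len(self.values):
            raise ValueError("composite starts and values must align")
        if len(self.composite_start_doys) and (
            np.diff(self.composite_start_doys) <= 0
        ).any():
            raise ValueError("composite start DOYs must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if ((finite < -1) | (finite > 1)).any():
            raise ValueError("GRVI values must lie in [-1, 1]")


@dataclass
class OnsetMap:
    """Per-pixel leaf-onset DOY for one year; NOT_DETECTED (-1) = none."""

    year: int
    geom: GridGeometry
    doy: np.ndarray

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy)
        if self.doy.shape != self.geom.shape:
            raise ValueError("onset array shape must match geometry")
        self.doy = self.doy.astype(np.int32)
        detected = self.doy[self.doy != NOT_DETECTED]
        if detected.size and ((detected < 1) | (detected > 366)).any():
            raise ValueError("detected onset DOYs must lie in [1, 366]")

    @property
    def detected(self) -> np.ndarray:
        return self.doy != NOT_DETECTED


def detect_onset(series: GRVISeries,
                 rule: DetectionRule = DetectionRule()) -> int | None:
    """First composite start whose GRVI exceeds the threshold, or None.

    Cloud/no-data composites (NaN) are treated as not exceeding.
    """
    if len(series.values) == 0:
        logger.warning("empty GRVI series for year %d", series.year)
        return None
    starts = series.composite_start_doys
    with np.errstate(invalid="ignore"):
        hit = np.isfinite(series.values) & (series.values > rule.threshold)
    hit &= starts <= rule.cutoff_doy
    idx = np.nonzero(hit)[0]
    return int(starts[idx[0]]) if idx.size else None


def detect_onset_map(values: np.ndarray, composite_start_doys: np.ndarray,
                     year: int, geom: GridGeometry,
                     rule: DetectionRule = DetectionRule(),
                     mask: np.ndarray | None = None) -> OnsetMap:
    """Apply the detection rule per pixel of a (composite, row, col) stack."""
    values = np.asarray(values, float)
    starts = np.asarray(composite_start_doys, int)
    if values.shape[0] != len(starts):
        raise ValueError("stack depth must equal number of composites")
    if values.shape[1:] != geom.shape:
        raise ValueError("stack shape must match geometry")
    with np.errstate(invalid="ignore"):
        hit = np.isfinite(values) & (values > rule.threshold)
    hit &= (starts <= rule.cutoff_doy)[:, None, None]
    any_hit = hit.any(axis=0)
    first = hit.argmax(axis=0)
    doy = np.where(any_hit, starts[first], NOT_DETECTED)
    if mask is not None:
        doy = np.where(mask, NOT_DETECTED, doy)
    return OnsetMap(year, geom, doy)
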
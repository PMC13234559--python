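"""Yearly vegetation-index composites and time-series metrics.

Scenes carry reflectance bands plus a boolean validity mask (cloud and
cloud-shadow pixels are invalid).  A yearly composite is the per-pixel
median of the index over valid observations in the selected months;
scenes above a scene-level cloud fraction are discarded outright.  The
before/after summaries are the per-pixel temporal mean and the OLS trend
against calendar year.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np

from .grid import GridGeometry, Raster

__all__ = [
    "Scene",
    "ImageStack",
    "vegetation_index",
    "yearly_composite",
    "yearly_series",
    "calc_ts_metrics",
    "TsMetrics",
]

log = logging.getLogger(__name__)

#: band requirements per index
_INDEX_BANDS = {"NDVI": ("nir", "red")}


@dataclass
class Scene:
    date: dt.date
    bands: dict[str, np.ndarray]
    mask: np.ndarray | None = None  # True = valid observation
    cloud_pct: float = 0.0


@dataclass
class ImageStack:
    scenes: list[Scene]
    grid: GridGeometry

    def __post_init__(self) -> None:
        for s in self.scenes:
            for name, arr in s.bands.items():
                if arr.shape != self.grid.shape:
                    raise ValueError(
                        f"band {name!r} of scene {s.date} does not match the grid"
                    )
            if s.mask is not None and s.mask.shape != self.grid.shape:
                raise ValueError(f"mask of scene {s.date} does not match the grid")


def vegetation_index(bands: dict[str, np.ndarray], index: str = "NDVI") -> np.ndarray:
    """Spectral index from a band dict; NDVI = (NIR - red)/(NIR + red).

    A zero denominator yields NaN; output is clipped to [-1, 1].
    """
    if index not in _INDEX_BANDS:
        raise ValueError(f"unknown index {index!r}; available: {sorted(_INDEX_BANDS)}")
    missing = [b for b in _INDEX_BANDS[index] if b not in bands]
    if missing:
        raise ValueError(f"missing band(s) {missing} for {index}")
    nir = np.asarray(bands["nir"], dtype=float)
    red = np.asarray(bands["red"], dtype=float)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, np.nan)
    return np.clip(out, -1.0, 1.0)


def yearly_composite(
    stack: ImageStack,
    year: int,
    months: tuple[int, ...] | range = range(1, 13),
    index: str = "NDVI",
    max_cloud: float | None = None,
) -> np.ndarray:
    """Median composite of the index over valid observations in a year.

    Scenes outside (year, months) or above ``max_cloud`` percent scene
    cloud cover are skipped.  Pixels with no valid observation are NaN;
    an even observation count uses the mean of the two middle values.
    """
    months = set(months)
    obs = []
    for s in stack.scenes:
        if s.date.year != year or s.date.month not in months:
            continue
        if max_cloud is not None and s.cloud_pct > max_cloud:
            continue
        vi = vegetation_index(s.bands, index)
        if s.mask is not None:
            vi = np.where(s.mask, vi, np.nan)
        obs.append(vi)
    if not obs:
        log.warning("no scenes for year %d after date/cloud filters", year)
        return np.full(stack.grid.shape, np.nan)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        return np.nanmedian(np.stack(obs), axis=0)


def yearly_series(
    stack: ImageStack,
    years: range | list[int],
    months=range(1, 13),
    index: str = "NDVI",
    max_cloud: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack of yearly composites: (years array, values [n_years, H, W])."""
    years = np.asarray(list(years), dtype=int)
    vals = np.stack([yearly_composite(stack, y, months, index, max_cloud) for y in years])
    return years, vals


@dataclass
class TsMetrics:
    """Per-pixel summaries of a yearly series.

    ``mean`` needs >= 1 non-missing year, ``trend`` (slope per calendar
    year) needs >= ``min_years``; ``intercept`` is the fitted value at
    the earliest/latest year of the period when requested.
    """

    mean: np.ndarray
    trend: np.ndarray
    n_years: np.ndarray
    intercept: np.ndarray | None = None
    intercept_at: str | None = None
    grid: GridGeometry | None = None

    def observables(self) -> dict[str, np.ndarray]:
        out = {"mean": self.mean, "trend": self.trend}
        if self.intercept is not None:
            out[f"intercept_{self.intercept_at}"] = self.intercept
        return out

    def rasters(self) -> dict[str, Raster]:
        if self.grid is None:
            raise ValueError("TsMetrics carries no grid")
        return {k: Raster(k, v, self.grid) for k, v in self.observables().items()}

    def resample_to(self, grid: GridGeometry) -> "TsMetrics":
        """Nearest-neighbour resampling of all metric layers to a grid."""
        from .grid import resample_nearest

        if self.grid is None:
            raise ValueError("TsMetrics carries no grid")
        rs = lambda a: None if a is None else resample_nearest(a, self.grid, grid)
        return TsMetrics(
            mean=rs(self.mean),
            trend=rs(self.trend),
            n_years=resample_nearest(self.n_years, self.grid, grid),
            intercept=rs(self.intercept),
            intercept_at=self.intercept_at,
            grid=grid,
        )


def calc_ts_metrics(
    years,
    values: np.ndarray,
    intercept_at: str | None = None,
    min_years: int = 3,
    grid: GridGeometry | None = None,
) -> TsMetrics:
    """Temporal mean and OLS trend of yearly values, NaN-aware per pixel.

    The trend regressor is the calendar year, centred per pixel on its
    observed years for numerical stability; missing years are simply
    omitted from the fit.  ``intercept_at`` in {"min", "max"} evaluates
    the fitted line at the first/last year of the period.
    """
    if intercept_at not in (None, "min", "max"):
        raise ValueError("intercept_at must be None, 'min' or 'max'")
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape[0] != years.size:
        raise ValueError("values first axis must match the number of years")

    valid = np.isfinite(values)
    n = valid.sum(axis=0)
    t = years.reshape((-1,) + (1,) * (values.ndim - 1))
    tv = np.where(valid, t, np.nan)
    vv = np.where(valid, values, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n >= 1, np.nansum(vv, axis=0) / n, np.nan)
        tbar = np.nansum(tv, axis=0) / n
        dt_ = np.where(valid, t - tbar, 0.0)
        dv = np.where(valid, values - mean, 0.0)
        sxx = np.sum(dt_ * dt_, axis=0)
        sxy = np.sum(dt_ * dv, axis=0)
        slope = np.where((n >= max(min_years, 2)) & (sxx > 0), sxy / sxx, np.nan)

    intercept = None
    if intercept_at is not None:
        t0 = years.min() if intercept_at == "min" else years.max()
        intercept = mean + slope * (t0 - tbar)
    return TsMetrics(
        mean=mean,
        trend=slope,
        n_years=n,
        intercept=intercept,
        intercept_at=intercept_at,
        grid=grid,
    )
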
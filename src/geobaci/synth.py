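"""Synthetic landscapes and outcome series with known ground truth.

The generator emulates the inputs of a pixel-based restoration impact
study: a smooth terrain field, a categorical land-cover map derived from
a second smooth field, a few roads, and intervention-site polygons whose
placement is confounded with the environment (sites preferentially sit
at, e.g., higher elevations).  Outcome series are yearly NDVI-like
values with an optional treatment effect injected at impact pixels in
the after period, rendered as per-scene NIR/red image stacks with cloud
masks so the full compositing pipeline can run on them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, box

from .grid import Affine, GridGeometry, Raster, resample_nearest
from .timeseries import ImageStack, Scene

__all__ = ["SyntheticLandscape", "make_landscape", "make_outcome_series", "OutcomeSeries"]

_DEFAULT_CONFOUNDING = {"elevation": 1.0, "dist_roads": -0.5}


def _smooth_field(rng: np.random.Generator, shape, n_bumps=12, rel_scale=(0.1, 0.3)):
    """Standardised sum of random Gaussian bumps: a smooth random surface."""
    h, w = shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    f = np.zeros(shape)
    for _ in range(n_bumps):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        s = rng.uniform(rel_scale[0], rel_scale[1]) * max(h, w)
        amp = rng.normal()
        f += amp * np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * s**2)))
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else a - a.mean()


@dataclass
class SyntheticLandscape:
    """A generated study area; ``truth`` records every generator parameter."""

    grid: GridGeometry
    dem: Raster
    lulc: Raster
    roads: list
    impact_polygons: list
    truth: dict = field(default_factory=dict)

    def impact_mask(self, grid: GridGeometry | None = None) -> np.ndarray:
        grid = grid or self.grid
        X, Y = grid.pixel_centers()
        union = shapely.unary_union(self.impact_polygons)
        shapely.prepare(union)
        return shapely.contains_xy(union, X.ravel(), Y.ravel()).reshape(grid.shape)


def make_landscape(
    seed: int = 0,
    size: tuple[int, int] = (90, 90),
    resolution: float = 60.0,
    n_classes: int = 3,
    confounding: dict | None = None,
    n_sites: int = 4,
    site_radius: int = 2,
    origin: tuple[float, float] = (500000.0, 6600000.0),
    crs: str = "EPSG:32735",
) -> SyntheticLandscape:
    """Generate a landscape with confounded intervention placement.

    ``confounding`` maps covariate name ("elevation", "dist_roads") to a
    logistic coefficient beta; site seed cells are drawn with selection
    weight sigmoid(sum beta_c * z_c) over pixels, so beta = 0 gives
    placement independent of the environment.  Each seed cell grows into
    a square intervention polygon of half-width ``site_radius`` pixels.
    """
    h, w = size
    if h < 20 or w < 20:
        raise ValueError("landscape must be at least 20x20 pixels")
    rng = np.random.default_rng(seed)
    grid = GridGeometry(w, h, Affine.north_up(origin[0], origin[1], resolution), crs)
    confounding = dict(_DEFAULT_CONFOUNDING if confounding is None else confounding)

    dem_field = _smooth_field(rng, size)
    dem = Raster("elevation", 800.0 + 150.0 * dem_field, grid)

    lc_field = _smooth_field(rng, size)
    qs = np.quantile(lc_field, np.linspace(0, 1, n_classes + 1)[1:-1])
    lulc = Raster(
        "landcover",
        np.digitize(lc_field, qs).astype(float) + 1,  # classes 1..K
        grid,
        categorical=True,
        scheme={k: f"class_{k}" for k in range(1, n_classes + 1)},
    )

    x0, y0, x1, y1 = grid.bounds
    roads = []
    for _ in range(2):
        if rng.random() < 0.5:  # west-east road
            p = [(x0, rng.uniform(y0, y1)), (rng.uniform(x0, x1), rng.uniform(y0, y1)),
                 (x1, rng.uniform(y0, y1))]
        else:  # south-north road
            p = [(rng.uniform(x0, x1), y0), (rng.uniform(x0, x1), rng.uniform(y0, y1)),
                 (rng.uniform(x0, x1), y1)]
        roads.append(LineString(p))

    # pixel-level placement covariates
    X, Y = grid.pixel_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    dist_roads = shapely.distance(pts, shapely.unary_union(roads)).reshape(size)
    z = {"elevation": _zscore(dem.values), "dist_roads": _zscore(dist_roads)}
    score = np.zeros(size)
    for name, beta in confounding.items():
        if name not in z:
            raise ValueError(f"unknown confounding covariate {name!r}")
        score += beta * z[name]
    weight = 1.0 / (1.0 + np.exp(-score))

    margin = site_radius + 2
    ok = np.zeros(size, dtype=bool)
    ok[margin:-margin, margin:-margin] = True
    weight = np.where(ok, weight, 0.0)
    prob = weight.ravel() / weight.sum()

    res = grid.resolution
    half = (site_radius + 0.5) * res
    seeds: list[tuple[int, int]] = []
    polys = []
    attempts = 0
    while len(seeds) < n_sites and attempts < 2000:
        attempts += 1
        k = rng.choice(prob.size, p=prob)
        r, c = np.unravel_index(k, size)
        if any(abs(r - r2) < 3 * site_radius and abs(c - c2) < 3 * site_radius for r2, c2 in seeds):
            continue
        seeds.append((r, c))
        cx, cy = grid.xy(r, c)
        polys.append(box(cx - half, cy - half, cx + half, cy + half))
    if len(polys) < n_sites:
        raise ValueError("could not place the requested number of non-overlapping sites")

    truth = {
        "seed": seed,
        "size": list(size),
        "resolution": resolution,
        "n_classes": n_classes,
        "confounding": confounding,
        "n_sites": n_sites,
        "site_radius": site_radius,
        "crs": crs,
    }
    return SyntheticLandscape(grid, dem, lulc, roads, polys, truth)


@dataclass
class OutcomeSeries:
    """Before/after image stacks plus the generating truth."""

    before: ImageStack
    after: ImageStack
    years_before: list[int]
    years_after: list[int]
    months: tuple[int, ...]
    truth: dict


def make_outcome_series(
    landscape: SyntheticLandscape,
    grid: GridGeometry | None = None,
    years_before=range(2002, 2012),
    years_after=range(2013, 2023),
    base_level: float = 0.3,
    trend: float = 0.0,
    delta: float = 0.1,
    sigma: float = 0.02,
    elev_level_coef: float = 0.05,
    elev_trend_coef: float = 0.0,
    obs_noise: float = 0.005,
    scenes_per_year: int = 2,
    months: tuple[int, ...] = (3, 4, 5),
    cloud_fraction: float = 0.1,
    seed: int = 0,
) -> OutcomeSeries:
    """Yearly NDVI outcome series with an injected treatment effect.

    The latent yearly value at pixel p and year t is

        v = base + trend*(t - t0) + elev_level_coef*z_elev
            + elev_trend_coef*z_elev*(t - t0) + field + eps(sigma)
            + delta * 1[p impact and t in after period]

    with a static smooth spatial field and iid yearly noise.  Setting
    ``elev_trend_coef`` nonzero makes the outcome TREND depend on the
    placement confounder, which biases naive (unmatched) estimates.
    Scenes render the value as NIR/red pairs (red fixed at 0.2) with
    small per-scene observation noise and random cloud masks.
    """
    grid = grid or landscape.grid
    rng = np.random.default_rng(seed)
    years_before = list(years_before)
    years_after = list(years_after)
    t0 = min(years_before)

    z_elev = _zscore(resample_nearest(landscape.dem.values, landscape.dem.grid, grid))
    static = 0.02 * _smooth_field(rng, grid.shape)
    impact = landscape.impact_mask(grid)

    def _stack(years: list[int], treated: bool) -> ImageStack:
        scenes = []
        for t in years:
            v = (
                base_level
                + trend * (t - t0)
                + elev_level_coef * z_elev
                + elev_trend_coef * z_elev * (t - t0)
                + static
                + rng.normal(0.0, sigma, grid.shape)
            )
            if treated:
                v = v + delta * impact
            for s in range(scenes_per_year):
                month = months[s % len(months)]
                obs = np.clip(v + rng.normal(0.0, obs_noise, grid.shape), -0.99, 0.99)
                red = np.full(grid.shape, 0.2)
                nir = red * (1 + obs) / (1 - obs)
                mask = rng.random(grid.shape) >= cloud_fraction
                scenes.append(
                    Scene(
                        date=dt.date(t, month, 15),
                        bands={"nir": nir, "red": red},
                        mask=mask,
                        cloud_pct=100.0 * float(1 - mask.mean()),
                    )
                )
        return ImageStack(scenes, grid)

    truth = {
        "delta": delta,
        "sigma": sigma,
        "base_level": base_level,
        "trend": trend,
        "elev_level_coef": elev_level_coef,
        "elev_trend_coef": elev_trend_coef,
        "obs_noise": obs_noise,
        "scenes_per_year": scenes_per_year,
        "cloud_fraction": cloud_fraction,
        "seed": seed,
        "years_before": years_before,
        "years_after": years_after,
        "months": list(months),
        "expected_contrast": -delta,
    }
    return OutcomeSeries(
        before=_stack(years_before, treated=False),
        after=_stack(years_after, treated=True),
        years_before=years_before,
        years_after=years_after,
        months=tuple(months),
        truth=truth,
    )


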
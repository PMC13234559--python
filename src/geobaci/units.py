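"""Pixel-based impact and candidate-control unit definition.

Impact units are grid cells whose centre falls inside an intervention
polygon.  Candidate control units come from a Euclidean buffer around the
intervention sites and/or an explicit control region, minus exclusion
polygons and minus a spillover buffer around the sites.  Buffering is
done on the vector geometries in the projected CRS (exact at coarse
resolutions), not via raster distance transforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from . import crs as _crs
from .grid import Affine, GridGeometry, LabelGrid, is_geographic

__all__ = ["UnitSpec", "build_grid", "create_control_candidates"]

log = logging.getLogger(__name__)


def _as_union(geoms) -> BaseGeometry | None:
    if geoms is None:
        return None
    if isinstance(geoms, BaseGeometry):
        return geoms
    geoms = list(geoms)
    if not geoms:
        return None
    return unary_union(geoms)


@dataclass(frozen=True)
class UnitSpec:
    """Parameters of impact/control unit construction.

    resolution
        Cell size in metres.
    control_from_buffer
        Width (m) of the neighbourhood around impact polygons from which
        candidate controls are drawn.
    control_from_polygon
        Explicit control-source polygons (alternative or additional to
        the buffer).
    control_exclude
        Polygons whose interior is excluded from the control pool
        (e.g. other intervention sites).
    exclude_impact_buffer
        Controls within this distance (m) of any impact polygon are
        excluded, guarding against spillover and misregistration.
    impact_inner_buffer
        Optional inward erosion (m) of the impact polygons before impact
        cells are selected; off by default.
    sample_impact / sample_control
        Retain a random fraction in (0, 1] of the respective pool.
    round_coords
        Decimal exponent for grid-origin rounding: -2 snaps the origin
        to the nearest 100 m.
    seed
        Seed of the single PRNG used for subsampling.
    """

    resolution: float
    control_from_buffer: float | None = None
    control_from_polygon: object | None = None
    control_exclude: object | None = None
    exclude_impact_buffer: float | None = None
    impact_inner_buffer: float | None = None
    sample_impact: float | None = None
    sample_control: float | None = None
    round_coords: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.control_from_buffer is None and _as_union(self.control_from_polygon) is None:
            raise ValueError(
                "at least one control source required: control_from_buffer "
                "or control_from_polygon"
            )
        for name in ("control_from_buffer", "exclude_impact_buffer", "impact_inner_buffer"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("sample_impact", "sample_control"):
            v = getattr(self, name)
            if v is not None and not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def _round_half_away(value: float, step: float) -> float:
    return math.copysign(math.floor(abs(value) / step + 0.5), value) * step


def _to_projected(geoms: Sequence[BaseGeometry], crs_in: str, crs_out: str | None):
    """Return geometries in a projected CRS, deriving UTM when needed."""
    geoms = [g for g in geoms if g is not None and not g.is_empty]
    if not geoms:
        raise ValueError("empty polygon set")
    if crs_out is not None and not is_geographic(crs_out):
        target = crs_out
    elif not is_geographic(crs_in):
        target = crs_in  # already projected: keep it
    else:
        target = _crs.utm_crs_from_centroid(geoms, crs_in)
    if is_geographic(crs_in):
        code = int(target.split(":")[1])
        south = code >= 32700
        zone = code - (32700 if south else 32600)
        geoms = [_crs.project_to_utm(g, zone, south) for g in geoms]
    return geoms, target


def build_grid(
    impact_polygons: Sequence[BaseGeometry],
    spec: UnitSpec,
    crs: str,
    target_crs: str | None = None,
) -> tuple[GridGeometry, list[BaseGeometry]]:
    """Lay out the analysis grid and return it with projected polygons.

    The grid covers the impact polygons expanded by the largest requested
    buffer, plus any explicit control-source polygons, with axes aligned
    to the CRS and, if ``round_coords`` is set, the origin snapped to the
    nearest 10^(-round_coords) metres (half away from zero).
    """
    geoms, proj = _to_projected(impact_polygons, crs, target_crs)
    pad = max(
        spec.control_from_buffer or 0.0,
        spec.exclude_impact_buffer or 0.0,
    )
    region = unary_union(geoms).buffer(pad, quad_segs=64) if pad > 0 else unary_union(geoms)
    ctl_poly = _as_union(spec.control_from_polygon)
    if ctl_poly is not None:
        region = unary_union([region, ctl_poly])
    x_min, y_min, x_max, y_max = region.bounds

    if spec.round_coords is not None:
        step = 10.0 ** (-spec.round_coords)
        ox = _round_half_away(x_min, step)
        oy = _round_half_away(y_max, step)
        # snapping must not shrink coverage: shift outward by one step if so
        if ox > x_min:
            ox -= step
        if oy < y_max:
            oy += step
    else:
        ox, oy = x_min, y_max

    res = spec.resolution
    width = max(1, int(math.ceil((x_max - ox) / res)))
    height = max(1, int(math.ceil((oy - y_min) / res)))
    grid = GridGeometry(width, height, Affine.north_up(ox, oy, res), proj)
    return grid, geoms


def _sample(rng: np.random.Generator, ids: np.ndarray, fraction: float | None) -> np.ndarray:
    """Retain round-half-even(fraction * n) ids, drawn without replacement."""
    if fraction is None or fraction >= 1.0:
        return ids
    k = round(fraction * ids.size)
    keep = rng.choice(ids, size=k, replace=False)
    return np.sort(keep)


def create_control_candidates(
    impact_polygons: Sequence[BaseGeometry],
    spec: UnitSpec,
    crs: str,
    target_crs: str | None = None,
    grid: GridGeometry | None = None,
) -> LabelGrid:
    """Label grid cells impact (1), candidate control (0) or excluded (NaN).

    A cell is impact iff its centre is covered by an (optionally eroded)
    impact polygon; it is control iff its centre lies in the control
    source region and outside the impact polygons, the exclusion
    polygons and the spillover buffer.  Subsampling, when requested, is
    applied to the final pools with a seeded PRNG over row-major cell
    order.

    Raises ``ValueError`` naming the filter that emptied a pool.
    """
    if grid is None:
        grid, geoms = build_grid(impact_polygons, spec, crs, target_crs)
    else:
        geoms, proj = _to_projected(impact_polygons, crs, grid.crs)
        if proj != grid.crs:
            raise ValueError(f"polygon CRS {proj} does not match grid CRS {grid.crs}")

    impact_union = unary_union(geoms)
    X, Y = grid.pixel_centers()
    xs, ys = X.ravel(), Y.ravel()

    impact_region = impact_union
    if spec.impact_inner_buffer:
        impact_region = impact_union.buffer(-spec.impact_inner_buffer, quad_segs=64)
    shapely.prepare(impact_region)
    impact_mask = shapely.contains_xy(impact_region, xs, ys)
    if not impact_mask.any():
        raise ValueError(
            "no impact pixels: polygons cover no cell centre at "
            f"resolution {spec.resolution}"
            + (" after impact_inner_buffer erosion" if spec.impact_inner_buffer else "")
        )

    sources = []
    if spec.control_from_buffer is not None:
        sources.append(impact_union.buffer(spec.control_from_buffer, quad_segs=64))
    ctl_poly = _as_union(spec.control_from_polygon)
    if ctl_poly is not None:
        sources.append(ctl_poly)
    control_src = unary_union(sources)
    shapely.prepare(control_src)
    control_mask = shapely.contains_xy(control_src, xs, ys)
    if not control_mask.any():
        raise ValueError("no control pixels: control source region covers no cell centre")

    shapely.prepare(impact_union)
    control_mask &= ~shapely.contains_xy(impact_union, xs, ys)
    if not control_mask.any():
        raise ValueError("no control pixels left after removing impact polygons")

    excl = _as_union(spec.control_exclude)
    if excl is not None:
        shapely.prepare(excl)
        control_mask &= ~shapely.contains_xy(excl, xs, ys)
        if not control_mask.any():
            raise ValueError("no control pixels left after control_exclude")

    if spec.exclude_impact_buffer:
        near = impact_union.buffer(spec.exclude_impact_buffer, quad_segs=64)
        shapely.prepare(near)
        control_mask &= ~shapely.contains_xy(near, xs, ys)
        if not control_mask.any():
            raise ValueError(
                f"no control pixels left after exclude_impact_buffer="
                f"{spec.exclude_impact_buffer}"
            )

    # never label a cell both: impact wins (only possible with erosion off edge cases)
    control_mask &= ~impact_mask

    rng = np.random.default_rng(spec.seed)
    impact_ids = _sample(rng, np.flatnonzero(impact_mask), spec.sample_impact)
    control_ids = _sample(rng, np.flatnonzero(control_mask), spec.sample_control)
    if impact_ids.size == 0:
        raise ValueError("no impact pixels left after sample_impact")
    if control_ids.size == 0:
        raise ValueError("no control pixels left after sample_control")

    labels = np.full(xs.size, np.nan)
    labels[impact_ids] = 1.0
    labels[control_ids] = 0.0
    log.info(
        "labelled %d impact and %d candidate control cells on %dx%d grid",
        impact_ids.size,
        control_ids.size,
        grid.height,
        grid.width,
    )
    return LabelGrid(grid, labels.reshape(grid.shape))
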
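"""Matching covariates: terrain derivatives, feature distances, land
cover, collation into a unit table, and multicollinearity screening.

Aspect is a circular variable and unsuitable for similarity metrics, so
it is decomposed into northness = cos(aspect) and eastness = sin(aspect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy.ndimage import map_coordinates
from shapely.ops import unary_union

from .grid import GridGeometry, LabelGrid, Raster

__all__ = [
    "terrain_derivatives",
    "distance_to_features",
    "encode_landcover",
    "collate_matching_layers",
    "expand_categoricals",
    "vif",
    "test_multicollinearity",
    "VifReport",
]

log = logging.getLogger(__name__)

TERRAIN_VARS = ("slope", "aspect", "northness", "eastness")


def terrain_derivatives(
    dem: Raster, which: tuple[str, ...] = ("slope", "northness", "eastness")
) -> dict[str, Raster]:
    """Slope/aspect/northness/eastness from a DEM by Horn's 3x3 method.

    Slope and aspect are in degrees; aspect is the downslope facing
    direction, clockwise from north.  Flat cells get slope 0 and
    northness = eastness = 0.  Edge cells use nearest-edge padding.
    """
    unknown = set(which) - set(TERRAIN_VARS)
    if unknown:
        raise ValueError(f"unknown terrain variables: {sorted(unknown)}")
    z = dem.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3 pixels")
    res = dem.grid.resolution
    zp = np.pad(z, 1, mode="edge")

    # Horn 1981 weights: (z[c+1] column sums with centre weight 2) / 8*res
    a, b, c = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    d, f = zp[1:-1, :-2], zp[1:-1, 2:]
    g, h, i = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * res)  # d z / d x (east)
    # rows increase southward on a north-up grid, so northward gradient
    # is (top block - bottom block)
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * res)

    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    flat = (gx == 0) & (gy == 0)
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0  # downslope facing
    northness = np.where(flat, 0.0, np.cos(np.radians(aspect)))
    eastness = np.where(flat, 0.0, np.sin(np.radians(aspect)))
    aspect = np.where(flat, np.nan, aspect)

    out = {
        "slope": slope,
        "aspect": aspect,
        "northness": northness,
        "eastness": eastness,
    }
    return {k: Raster(k, out[k], dem.grid) for k in which}


def distance_to_features(
    grid: GridGeometry,
    features,
    class_filter: str | None = None,
    class_values: list | None = None,
    hierarchy: list | None = None,
    name: str = "dist_features",
) -> Raster:
    """Euclidean distance (m) from each cell centre to the nearest feature.

    ``class_filter`` selects features by class attribute.  A trailing
    ``+`` (e.g. ``"track+"``) keeps the named class and every class
    ranked above it in ``hierarchy`` (an ordered list, lowest first).
    ``features`` is either a sequence of geometries or a
    ``(geometries, classes)`` pair / object with ``geoms`` and
    ``attributes`` (a DataFrame with a ``class`` column).
    """
    geoms, classes = _geoms_and_classes(features, class_values)
    if class_filter is not None:
        if classes is None:
            raise ValueError("class_filter given but features carry no classes")
        keep = _resolve_class_filter(class_filter, hierarchy)
        geoms = [g for g, c in zip(geoms, classes) if c in keep]
        if not geoms:
            raise ValueError(f"no features left after class_filter={class_filter!r}")
    if not geoms:
        raise ValueError("empty feature set")
    union = unary_union(geoms)
    X, Y = grid.pixel_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    d = shapely.distance(pts, union).reshape(grid.shape)
    return Raster(name, d, grid)


def _geoms_and_classes(features, class_values):
    if hasattr(features, "geoms") and hasattr(features, "attributes"):
        geoms = list(features.geoms)
        attrs = features.attributes
        classes = list(attrs["class"]) if attrs is not None and "class" in attrs else None
        return geoms, classes
    if (
        isinstance(features, tuple)
        and len(features) == 2
        and not hasattr(features[0], "geom_type")
    ):
        return list(features[0]), list(features[1])
    return list(features), class_values


def _resolve_class_filter(class_filter: str, hierarchy: list | None) -> set:
    if class_filter.endswith("+"):
        base = class_filter[:-1]
        if hierarchy is None:
            raise ValueError("'+' class filter requires an ordered class hierarchy")
        if base not in hierarchy:
            raise ValueError(f"class {base!r} not in hierarchy {hierarchy}")
        return set(hierarchy[hierarchy.index(base):])
    return {class_filter}


def encode_landcover(lulc: Raster, scheme: dict | None = None, name: str = "landcover") -> Raster:
    """Validate and tag an integer land-cover raster as categorical.

    ``scheme`` maps class codes to labels; codes present in the raster
    but absent from the scheme are an error.  The class column stays
    level-coded in the unit table and is expanded into K-1 indicators
    (reference level = most frequent class) at model time.
    """
    vals = lulc.values
    present = np.unique(vals[np.isfinite(vals)]).astype(int)
    if scheme is not None:
        missing = [int(v) for v in present if int(v) not in scheme]
        if missing:
            raise ValueError(f"land-cover classes {missing} absent from scheme {sorted(scheme)}")
    return Raster(name, vals, lulc.grid, categorical=True, scheme=scheme)


def _resample_to(layer: Raster, grid: GridGeometry, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample a layer at world points: nearest for categorical, bilinear else."""
    t = layer.grid.transform
    col = (x - t.c) / t.a - 0.5
    row = (y - t.f) / t.e - 0.5
    x0, y0, x1, y1 = layer.grid.bounds
    outside = (x < x0) | (x > x1) | (y < y0) | (y > y1)
    if layer.categorical:
        r = np.clip(np.rint(row).astype(int), 0, layer.grid.height - 1)
        c = np.clip(np.rint(col).astype(int), 0, layer.grid.width - 1)
        out = layer.values[r, c]
    else:
        # bilinear with edge clamping (half-pixel margins included)
        out = map_coordinates(layer.values, [row, col], order=1, mode="nearest")
    out = np.asarray(out, dtype=float)
    out[outside] = np.nan
    return out


def collate_matching_layers(label_grid: LabelGrid, layers: list[Raster]) -> pd.DataFrame:
    """One row per labelled cell: unit_id, x, y, treatment, covariates.

    Layers on a different grid geometry (same CRS) are resampled to the
    unit grid — nearest-neighbour for categorical layers, bilinear for
    continuous ones.  Rows with any missing covariate are dropped with a
    logged count.  The returned frame records categorical column names
    in ``df.attrs["categorical"]``.
    """
    names = [lyr.name for lyr in layers]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicated covariate names: {sorted(dupes)}")

    df = label_grid.unit_table()
    grid = label_grid.grid
    flat_ids = df["unit_id"].to_numpy()
    categorical: list[str] = []
    for lyr in layers:
        if lyr.grid.same_geometry(grid):
            vals = lyr.values.ravel()[flat_ids]
        else:
            if lyr.grid.crs != grid.crs:
                raise ValueError(
                    f"layer {lyr.name!r} CRS {lyr.grid.crs} != grid CRS {grid.crs}"
                )
            vals = _resample_to(lyr, grid, df["x"].to_numpy(), df["y"].to_numpy())
        df[lyr.name] = vals
        if lyr.categorical:
            categorical.append(lyr.name)

    n0 = len(df)
    df = df.dropna(axis=0)
    dropped = n0 - len(df)
    if dropped:
        log.warning("%d units dropped for missing covariate values", dropped)
    if df.empty:
        raise ValueError("all units dropped: every row had a missing covariate")
    if df["treatment"].nunique() < 2:
        raise ValueError("unit table lost one treatment class after dropping missing rows")
    df = df.reset_index(drop=True)
    df.attrs["categorical"] = categorical
    df.attrs["dropped_missing"] = dropped
    return df


def covariate_columns(table: pd.DataFrame) -> list[str]:
    base = {"unit_id", "x", "y", "treatment"}
    return [c for c in table.columns if c not in base]


def expand_categoricals(table: pd.DataFrame) -> pd.DataFrame:
    """Design columns: continuous covariates plus K-1 class indicators.

    The reference level of each categorical covariate is its most
    frequent class.  A single-class categorical yields no columns and is
    dropped with a warning.
    """
    cats = table.attrs.get("categorical", [])
    out = {}
    for col in covariate_columns(table):
        if col not in cats:
            out[col] = table[col].astype(float)
            continue
        counts = table[col].value_counts()
        if len(counts) < 2:
            log.warning("categorical covariate %r has a single class: dropped", col)
            continue
        ref = counts.index[0]
        for level in sorted(v for v in counts.index if v != ref):
            key = f"{col}_{int(level) if float(level).is_integer() else level}"
            out[key] = (table[col] == level).astype(float)
    return pd.DataFrame(out, index=table.index)


@dataclass
class VifReport:
    """Variance-inflation factors and the screening outcome."""

    vif: pd.Series
    threshold: float
    flagged: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    correlation: pd.DataFrame | None = None

    def __str__(self) -> str:
        lines = ["VIF report (threshold %.3g)" % self.threshold]
        for name, v in self.vif.items():
            mark = " *" if name in self.flagged else ""
            lines.append(f"  {name:<24s} {v:>10.4g}{mark}")
        if self.dropped:
            lines.append("dropped: " + ", ".join(self.dropped))
        return "\n".join(lines)


def vif(table: pd.DataFrame, threshold: float = 5.0) -> VifReport:
    """VIF_j = 1/(1 - R^2_j), R^2_j from regressing covariate j on the rest.

    Categorical covariates enter as their indicator columns.  Perfect
    collinearity is reported as +inf and flagged.
    """
    X = expand_categoricals(table)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 covariate columns")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("VIF needs more rows than covariates + 1")
    vals = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        vals[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    series = pd.Series(vals, name="vif")
    flagged = [c for c, v in series.items() if v > threshold]
    return VifReport(vif=series, threshold=threshold, flagged=flagged)


def test_multicollinearity(
    table: pd.DataFrame,
    threshold: float = 5.0,
    policy: str = "auto-drop-worst",
) -> tuple[pd.DataFrame, VifReport]:
    """Screen the unit table for multicollinearity.

    ``auto-drop-worst`` iteratively removes the highest-VIF covariate
    (a categorical covariate is removed whole when one of its indicators
    is worst) until all VIF <= threshold; ``report-only`` leaves the
    table untouched.  The report carries the correlation matrix of the
    continuous covariates for plotting.
    """
    if policy not in ("auto-drop-worst", "report-only"):
        raise ValueError(f"unknown policy {policy!r}")
    cats = table.attrs.get("categorical", [])
    work = table.copy()
    work.attrs.update(table.attrs)
    dropped: list[str] = []
    while True:
        report = vif(work, threshold)
        if policy == "report-only" or not report.flagged:
            break
        worst_col = report.vif.idxmax()
        # map an indicator column back to its categorical parent
        parent = next((c for c in cats if worst_col.startswith(c + "_")), worst_col)
        remaining = [c for c in covariate_columns(work) if c != parent]
        if len(remaining) < 1:
            raise ValueError(
                f"dropping {parent!r} would leave no covariates; "
                "review the covariate set instead"
            )
        log.info("dropping covariate %r (VIF=%.3g)", parent, report.vif[worst_col])
        dropped.append(parent)
        work = work.drop(columns=[parent])
        work.attrs["categorical"] = [c for c in cats if c != parent]
        if expand_categoricals(work).shape[1] < 2:
            # a lone covariate cannot be collinear with anything
            cols = expand_categoricals(work).columns
            report = VifReport(pd.Series(1.0, index=cols, name="vif"), threshold)
            break
    report.dropped = dropped
    cont = [
        c for c in covariate_columns(work) if c not in work.attrs.get("categorical", [])
    ]
    report.correlation = work[cont].corr() if len(cont) >= 2 else None
    return work, report
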
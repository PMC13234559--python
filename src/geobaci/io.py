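"""File I/O: GeoJSON vectors, georeferenced TIFF rasters, scene manifests.

Rasters are written as plain TIFF via tifffile with a JSON sidecar
(``<file>.aux.json``) holding the geotransform, CRS, nodata and band
names; reading restores them bit-exact.  Vector data is GeoJSON
(GeoPackage requires a GDAL stack and is rejected with a clear error).
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape

from .grid import Affine, GridGeometry, Raster
from .timeseries import ImageStack, Scene

__all__ = [
    "VectorLayer",
    "read_vector",
    "write_vector",
    "read_raster",
    "write_raster",
    "read_manifest",
    "write_stack",
]


@dataclass
class VectorLayer:
    """Geometries + attribute table + CRS."""

    geoms: list
    attributes: pd.DataFrame
    crs: str = "EPSG:4326"

    def __len__(self) -> int:
        return len(self.geoms)


def _geojson_crs(obj: dict) -> str:
    crs = obj.get("crs")
    if crs is None:
        return "EPSG:4326"  # GeoJSON default
    name = crs.get("properties", {}).get("name", "")
    m = re.search(r"EPSG(?::|::)(\d+)", name)
    if m:
        return f"EPSG:{m.group(1)}"
    return name or "EPSG:4326"


def read_vector(path, layer: str | None = None, where: str | None = None) -> VectorLayer:
    """Read a GeoJSON feature collection with optional attribute filter.

    ``where`` is a boolean expression over attribute columns, e.g.
    ``"Planting_date==2012 && Lifestock_exclusion==0"`` (``&&``/``||``
    are accepted alongside ``&``/``|``).  An unknown column or an empty
    result is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".gpkg":
        raise ValueError(
            "GeoPackage input is not supported (no GDAL backend available); "
            "convert to GeoJSON"
        )
    obj = json.loads(path.read_text())
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
    geoms = [shape(f["geometry"]) for f in feats]
    attrs = pd.DataFrame([f.get("properties") or {} for f in feats])
    crs = _geojson_crs(obj)

    if where:
        expr = where.replace("&&", "&").replace("||", "|")
        unknown = [
            tok
            for tok in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", expr)
            if tok not in attrs.columns and tok not in ("and", "or", "not", "True", "False")
        ]
        if unknown:
            raise ValueError(f"unknown column(s) in filter: {unknown}")
        mask = attrs.eval(expr)
        geoms = [g for g, m in zip(geoms, mask) if m]
        attrs = attrs[mask.to_numpy()].reset_index(drop=True)
        if not geoms:
            raise ValueError(f"filter {where!r} matched no features")
    return VectorLayer(geoms, attrs, crs)


def write_vector(path, layer: VectorLayer) -> None:
    feats = []
    records = layer.attributes.to_dict("records") if len(layer.attributes) else [{}] * len(layer.geoms)
    for geom, props in zip(layer.geoms, records):
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    obj = {
        "type": "FeatureCollection",
        "features": feats,
        "crs": {"type": "name", "properties": {"name": f"urn:ogc:def:crs:{layer.crs.replace(':', '::')}"}},
    }
    Path(path).write_text(json.dumps(obj))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def write_raster(path, raster, nodata: float = -9999.0) -> None:
    """Write one Raster or a {name: Raster} band dict with a JSON sidecar."""
    path = Path(path)
    if isinstance(raster, Raster):
        bands = {raster.name: raster}
    else:
        bands = dict(raster)
    grids = {id(b.grid): b.grid for b in bands.values()}
    grid = next(iter(grids.values()))
    for b in bands.values():
        if not b.grid.same_geometry(grid):
            raise ValueError("all bands must share one grid geometry")
    arr = np.stack([b.values for b in bands.values()]).astype("float64")
    arr = np.where(np.isfinite(arr), arr, nodata)
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "transform": list(grid.transform.to_tuple()),
        "crs": grid.crs,
        "nodata": nodata,
        "bands": [
            {"name": b.name, "categorical": b.categorical, "scheme": b.scheme}
            for b in bands.values()
        ],
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_raster(path, name: str | None = None):
    """Read a sidecar-georeferenced TIFF; single band -> Raster, else dict."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    nodata = meta.get("nodata")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    t = Affine(*meta["transform"])
    grid = GridGeometry(arr.shape[2], arr.shape[1], t, meta["crs"])
    out = {}
    for band, info in zip(arr, meta["bands"]):
        scheme = info.get("scheme")
        if scheme is not None:
            scheme = {int(k): v for k, v in scheme.items()}
        out[info["name"]] = Raster(
            name or info["name"], band, grid,
            categorical=info.get("categorical", False), scheme=scheme,
        )
    if len(out) == 1:
        return next(iter(out.values()))
    return out


def write_stack(directory, stack: ImageStack, prefix: str = "scene") -> Path:
    """Write an image stack as per-scene TIFFs plus a manifest CSV.

    Manifest columns: path, date, cloud_pct.  Each scene TIFF holds the
    reflectance bands plus a ``valid_mask`` band (1 = valid).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / f"{prefix}_manifest.csv"
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "date", "cloud_pct"])
        for k, s in enumerate(stack.scenes):
            fn = directory / f"{prefix}_{k:04d}.tif"
            bands = {n: Raster(n, v, stack.grid) for n, v in s.bands.items()}
            if s.mask is not None:
                bands["valid_mask"] = Raster("valid_mask", s.mask.astype(float), stack.grid)
            write_raster(fn, bands)
            w.writerow([fn.name, s.date.isoformat(), f"{s.cloud_pct:.2f}"])
    return manifest


def read_manifest(path, grid: GridGeometry | None = None) -> ImageStack:
    """Read a scene manifest CSV (path, date, cloud_pct) into an ImageStack."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("path", "date"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col!r}")
    scenes = []
    stack_grid = grid
    for rec in df.itertuples(index=False):
        bands = read_raster(path.parent / rec.path)
        if isinstance(bands, Raster):
            bands = {bands.name: bands}
        g = next(iter(bands.values())).grid
        if stack_grid is None:
            stack_grid = g
        elif not g.same_geometry(stack_grid):
            raise ValueError(f"scene {rec.path} grid differs from the stack grid")
        mask_r = bands.pop("valid_mask", None)
        scenes.append(
            Scene(
                date=dt.date.fromisoformat(str(rec.date)),
                bands={n: b.values for n, b in bands.items()},
                mask=None if mask_r is None else mask_r.values >= 0.5,
                cloud_pct=float(getattr(rec, "cloud_pct", 0.0)),
            )
        )
    return ImageStack(scenes, stack_grid)
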
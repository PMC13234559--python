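"""UTM zone selection and WGS84 -> UTM forward projection.

Implements the standard transverse-Mercator series (WGS84 ellipsoid,
scale factor 0.9996, false easting 500 km, false northing 10 000 km on
the southern hemisphere), accurate to well under a metre within a UTM
zone — sufficient for placing analysis grids.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

__all__ = ["utm_zone", "utm_epsg", "utm_crs_from_centroid", "lonlat_to_utm", "project_to_utm"]

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_K0 = 0.9996


def utm_zone(lon: float, lat: float) -> tuple[int, bool]:
    """Return (zone number, southern-hemisphere flag) for a lon/lat point.

    UTM is undefined outside latitudes [-80, 84].
    """
    if not (-80.0 <= lat <= 84.0):
        raise ValueError(f"latitude {lat} outside UTM range [-80, 84]")
    lon = ((lon + 180.0) % 360.0) - 180.0
    zone = int(np.floor((lon + 180.0) / 6.0)) + 1
    zone = min(zone, 60)
    return zone, lat < 0


def utm_epsg(zone: int, south: bool) -> str:
    return f"EPSG:{(32700 if south else 32600) + zone}"


def utm_crs_from_centroid(geoms, crs: str = "EPSG:4326") -> str:
    """UTM CRS of the centroid of a geometry collection in lon/lat.

    The centroid is computed on the unioned geometry in geographic
    coordinates, mirroring the convention of picking the UTM zone that
    contains the study area's centre.
    """
    from .grid import is_geographic

    if not is_geographic(crs):
        raise ValueError(f"centroid CRS {crs!r} is not geographic")
    if isinstance(geoms, BaseGeometry):
        geoms = [geoms]
    geoms = list(geoms)
    if not geoms:
        raise ValueError("empty geometry set")
    c = unary_union(geoms).centroid
    zone, south = utm_zone(c.x, c.y)
    return utm_epsg(zone, south)


def lonlat_to_utm(lon, lat, zone: int, south: bool):
    """Forward transverse-Mercator projection of lon/lat arrays (degrees)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    a, f = _WGS84_A, _WGS84_F
    e2 = f * (2 - f)
    ep2 = e2 / (1 - e2)
    phi = np.radians(lat)
    lam = np.radians(lon)
    lam0 = np.radians(zone * 6.0 - 183.0)

    sin_phi, cos_phi, tan_phi = np.sin(phi), np.cos(phi), np.tan(phi)
    N = a / np.sqrt(1 - e2 * sin_phi**2)
    T = tan_phi**2
    C = ep2 * cos_phi**2
    A = cos_phi * (lam - lam0)

    # meridian arc length from the equator
    M = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )

    x = (
        _K0
        * N
        * (
            A
            + (1 - T + C) * A**3 / 6
            + (5 - 18 * T + T**2 + 72 * C - 58 * ep2) * A**5 / 120
        )
        + 500000.0
    )
    y = _K0 * (
        M
        + N
        * tan_phi
        * (
            A**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * A**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * ep2) * A**6 / 720
        )
    )
    if south:
        y = y + 10000000.0
    return x, y


def project_to_utm(geom: BaseGeometry, zone: int, south: bool) -> BaseGeometry:
    """Reproject a shapely geometry from lon/lat to UTM metres."""

    def _tx(coords: np.ndarray) -> np.ndarray:
        x, y = lonlat_to_utm(coords[:, 0], coords[:, 1], zone, south)
        return np.column_stack([x, y])

    return shapely.transform(geom, _tx)
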
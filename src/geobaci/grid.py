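"""Regular raster grids in a projected CRS.

A grid is defined by an affine geotransform (north-up, square pixels in
metres), a width/height in pixels, and a CRS identifier.  Cells are
half-open, indexed row-major from the top-left corner; a point belongs to
the cell whose half-open extent contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "Affine",
    "GridGeometry",
    "Raster",
    "LabelGrid",
    "is_geographic",
    "resample_nearest",
]

#: EPSG codes treated as geographic (degree) coordinate systems.  Anything
#: else is assumed to be projected with metre units, which is what every
#: UTM / national grid this package emits uses.
_GEOGRAPHIC_EPSG = {4326, 4269, 4258, 4267}


def is_geographic(crs: str) -> bool:
    """True if *crs* (an ``"EPSG:xxxx"`` string) is a geographic CRS."""
    if crs is None:
        raise ValueError("CRS is undefined")
    code = str(crs).upper().replace("EPSG:", "").strip()
    try:
        return int(code) in _GEOGRAPHIC_EPSG
    except ValueError:
        return False


@dataclass(frozen=True)
class Affine:
    """Affine geotransform mapping (col, row) -> (x, y).

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f``.  For the
    north-up grids produced here ``b = d = 0``, ``a = resolution`` and
    ``e = -resolution``.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __mul__(self, colrow: tuple[float, float]) -> tuple[float, float]:
        col, row = colrow
        return (
            self.a * col + self.b * row + self.c,
            self.d * col + self.e * row + self.f,
        )

    def to_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)

    @classmethod
    def north_up(cls, x_min: float, y_max: float, resolution: float) -> "Affine":
        return cls(resolution, 0.0, x_min, 0.0, -resolution, y_max)


@dataclass(frozen=True)
class GridGeometry:
    """Shape + geotransform + CRS of a raster grid."""

    width: int
    height: int
    transform: Affine
    crs: str

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"degenerate grid {self.width}x{self.height}")
        if self.transform.a <= 0 or self.transform.e >= 0:
            raise ValueError("grid must be north-up with positive pixel size")
        if abs(self.transform.a) != abs(self.transform.e):
            raise ValueError("pixels must be square")
        if is_geographic(self.crs):
            raise ValueError(f"grid CRS must be projected, got {self.crs!r}")

    @property
    def resolution(self) -> float:
        return self.transform.a

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the grid extent."""
        x0, y1 = self.transform * (0, 0)
        x1, y0 = self.transform * (self.width, self.height)
        return (x0, y0, x1, y1)

    def xy(self, row, col, center: bool = True):
        """World coordinates of pixel (row, col); centre by default."""
        off = 0.5 if center else 0.0
        col = np.asarray(col, dtype=float) + off
        row = np.asarray(row, dtype=float) + off
        t = self.transform
        return t.a * col + t.b * row + t.c, t.d * col + t.e * row + t.f

    def rowcol(self, x, y):
        """Pixel indices containing world point(s) (half-open cells)."""
        t = self.transform
        col = np.floor((np.asarray(x, dtype=float) - t.c) / t.a).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - t.f) / t.e).astype(int)
        return row, col

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (height, width) of all cell centres."""
        cols = np.arange(self.width)
        rows = np.arange(self.height)
        cgrid, rgrid = np.meshgrid(cols, rows)
        return self.xy(rgrid, cgrid)

    def same_geometry(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and all(
                abs(p - q) <= tol
                for p, q in zip(self.transform.to_tuple(), other.transform.to_tuple())
            )
        )


@dataclass
class Raster:
    """A named single-band raster on a :class:`GridGeometry`.

    Missing data is NaN.  ``categorical`` marks integer class layers
    (resampled nearest-neighbour, expanded to indicators at model time);
    ``scheme`` optionally maps class codes to labels.
    """

    name: str
    values: np.ndarray
    grid: GridGeometry
    categorical: bool = False
    scheme: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster {self.name!r} shape {self.values.shape} does not match "
                f"grid {self.grid.shape}"
            )


def resample_nearest(values: np.ndarray, src: "GridGeometry", dst: "GridGeometry") -> np.ndarray:
    """Sample a source-grid array at the destination grid's cell centres.

    Nearest-neighbour (cell membership); centres outside the source
    extent clamp to the edge cell.
    """
    if src.same_geometry(dst):
        return values
    if src.crs != dst.crs:
        raise ValueError(f"CRS mismatch: {src.crs} vs {dst.crs}")
    X, Y = dst.pixel_centers()
    r, c = src.rowcol(X.ravel(), Y.ravel())
    r = np.clip(r, 0, src.height - 1)
    c = np.clip(c, 0, src.width - 1)
    return np.asarray(values)[r, c].reshape(dst.shape)


@dataclass
class LabelGrid:
    """Impact/control unit labels on a grid.

    Per-pixel values: 1 = impact unit, 0 = candidate control unit,
    NaN = excluded.  Unit ids are row-major flat pixel indices.
    """

    grid: GridGeometry
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        finite = self.labels[np.isfinite(self.labels)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("labels must be 1 (impact), 0 (control) or NaN")
        if not (finite == 1).any():
            raise ValueError("no impact pixels")
        if not (finite == 0).any():
            raise ValueError("no control pixels")

    @property
    def impact_ids(self) -> np.ndarray:
        return np.flatnonzero(self.labels.ravel() == 1)

    @property
    def control_ids(self) -> np.ndarray:
        return np.flatnonzero(self.labels.ravel() == 0)

    @property
    def unit_ids(self) -> np.ndarray:
        return np.flatnonzero(np.isfinite(self.labels.ravel()))

    def unit_table(self) -> "pd.DataFrame":
        """Base unit table: unit_id, x, y (cell centres), treatment."""
        import pandas as pd

        ids = self.unit_ids
        rows, cols = np.unravel_index(ids, self.grid.shape)
        x, y = self.grid.xy(rows, cols)
        return pd.DataFrame(
            {
                "unit_id": ids,
                "x": x,
                "y": y,
                "treatment": self.labels.ravel()[ids].astype(int),
            }
        )

    def iter_units(self) -> Iterator[tuple[int, float, float]]:
        for uid, x, y, _ in self.unit_table().itertuples(index=False):
            yield uid, x, y
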
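"""Terrain rasters: elevation grids, percent slope, and the statutory gradient rule.

The elevation input is a bare-earth digital terrain model (DTM) on a regular
square grid. Slope is computed with the Horn 3x3 finite-difference operator and
reported in percent (rise/run x 100), the unit used throughout the
accessibility model. French accessibility law (Law No. 2005-102 of 2005)
defines an obstacle-free path as one whose gradient does not exceed 5%; that
predicate is exposed here as :func:`is_statutory`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Raster",
    "ElevationRaster",
    "SlopeRaster",
    "STATUTORY_MAX_GRADIENT",
    "slope_percent",
    "is_statutory",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: Maximum percent gradient of a statutorily obstacle-free path.
STATUTORY_MAX_GRADIENT = 5.0


@dataclass
class Raster:
    """A regular square-celled raster in a projected metric CRS.

    ``origin_x``/``origin_y`` locate the *top-left corner* of the grid (the
    upper-left corner of cell ``[0, 0]``); ``values`` is row-major from the
    top-left, so row index increases southward. ``nodata`` marks missing cells.
    """

    origin_x: float
    origin_y: float
    cellsize: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cellsize > 0:
            raise ValueError(f"cell size must be positive, got {self.cellsize}")

    # -- geometry ----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full cell extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cellsize,
            self.origin_x + self.n_cols * self.cellsize,
            self.origin_y,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of every cell-center coordinate."""
        cs = self.cellsize
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return self.values != self.nodata

    # -- sampling ----------------------------------------------------------

    def sample(self, x, y):
        """Bilinearly interpolate raster values at planar coordinates.

        Accepts scalars or arrays. Coordinates between the outermost cell
        centers and the raster edge are clamped (edge replication). Points
        outside the raster extent raise ``ValueError``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.bounds
        bad = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
        if np.any(bad):
            i = int(np.argmax(np.atleast_1d(bad)))
            bx = float(np.atleast_1d(x)[i])
            by = float(np.atleast_1d(y)[i])
            raise ValueError(
                f"point ({bx:.3f}, {by:.3f}) lies outside the raster extent "
                f"{self.bounds}"
            )
        col = (x - self.origin_x) / self.cellsize - 0.5
        row = (self.origin_y - y) / self.cellsize - 0.5
        out = ndimage.map_coordinates(
            self.values, [np.atleast_1d(row), np.atleast_1d(col)],
            order=1, mode="nearest",
        )
        return out.reshape(np.shape(x)) if np.shape(x) else float(out[0])


class ElevationRaster(Raster):
    """Bare-earth elevation in meters."""


class SlopeRaster(Raster):
    """Percent slope; non-nodata values are always >= 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        valid = self.values[self.values != self.nodata]
        if valid.size and np.any(valid < 0):
            raise ValueError("slope raster contains negative percent values")


def slope_percent(dtm: ElevationRaster) -> SlopeRaster:
    """Percent slope from a DTM using the Horn 3x3 operator.

    Border cells are handled by edge replication, so the output covers the
    same grid as the input. Any 3x3 window touching a nodata cell yields
    nodata. On a planar surface the Horn operator is exact, so interior cells
    of a ramp of grade g% report exactly g.
    """
    if dtm.n_rows < 3 or dtm.n_cols < 3:
        raise ValueError(
            f"slope needs at least a 3x3 raster, got {dtm.n_rows}x{dtm.n_cols}"
        )
    z = np.pad(dtm.values, 1, mode="edge")
    cs = dtm.cellsize
    # Horn kernel: weighted central differences over the 3x3 neighborhood.
    dzdx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8.0 * cs)
    dzdy = (
        (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
    ) / (8.0 * cs)
    slope = 100.0 * np.hypot(dzdx, dzdy)
    invalid = dtm.values == dtm.nodata
    if invalid.any():
        spread = ndimage.maximum_filter(invalid.astype(np.uint8), size=3)
        slope[spread.astype(bool)] = dtm.nodata
    return SlopeRaster(dtm.origin_x, dtm.origin_y, cs, slope, dtm.nodata)


def is_statutory(gradient: float) -> bool:
    """True iff a percent gradient satisfies the statutory <= 5% rule."""
    if gradient < 0:
        raise ValueError(f"gradient must be non-negative, got {gradient}")
    return gradient <= STATUTORY_MAX_GRADIENT


# -- Esri ASCII grid IO ----------------------------------------------------


def read_ascii_grid(path, cls=Raster) -> Raster:
    """Read an Esri ASCII grid (.asc)."""
    with open(path) as fh:
        text = fh.read()
    return parse_ascii_grid(text, cls=cls)


def parse_ascii_grid(text: str, cls=Raster) -> Raster:
    tokens = text.split()
    header: dict[str, float] = {}
    i = 0
    # header is KEY value pairs until the first bare number
    while i < len(tokens):
        key = tokens[i].lower()
        if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            header[key] = float(tokens[i + 1])
            i += 2
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid header missing {req.upper()}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    data = np.array(tokens[i:], dtype=float)
    if data.size != nrows * ncols:
        raise ValueError(
            f"ASCII grid body has {data.size} values, expected {nrows * ncols}"
        )
    values = data.reshape(nrows, ncols)
    origin_x = header["xllcorner"]
    origin_y = header["yllcorner"] + nrows * header["cellsize"]
    return cls(origin_x, origin_y, header["cellsize"], values, nodata)


def format_ascii_grid(raster: Raster, fmt: str = "%.6g") -> str:
    xll = raster.origin_x
    yll = raster.origin_y - raster.n_rows * raster.cellsize
    buf = io.StringIO()
    buf.write(f"NCOLS {raster.n_cols}\n")
    buf.write(f"NROWS {raster.n_rows}\n")
    buf.write(f"XLLCORNER {xll:.6f}\n")
    buf.write(f"YLLCORNER {yll:.6f}\n")
    buf.write(f"CELLSIZE {raster.cellsize:.6f}\n")
    buf.write(f"NODATA_VALUE {raster.nodata:.6f}\n")
    for row in raster.values:
        buf.write(" ".join(fmt % v for v in row))
        buf.write("\n")
    return buf.getvalue()


def write_ascii_grid(raster: Raster, path, fmt: str = "%.6g") -> None:
    """Write an Esri ASCII grid; reading it back reproduces the raster."""
    with open(path, "w") as fh:
        fh.write(format_ascii_grid(raster, fmt=fmt))
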
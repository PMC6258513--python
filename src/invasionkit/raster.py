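"""Habitat-suitability / intensity rasters and ESRI ASCII grid I/O.

Cells are half-open in world coordinates: a cell with lower-left corner
(x0, y0) covers [x0, x0+cs) x [y0, y0+cs), so a point on a shared interior
edge belongs to the cell on the higher-coordinate side and every point maps
to exactly one cell. Row 0 of `values` is the top row, as in ESRI ASCII.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SuitabilityRaster", "read_esri_ascii", "write_esri_ascii"]


@dataclass
class SuitabilityRaster:
    """Gridded values in [0, 1] (or a no-data sentinel) with a geotransform.

    Parameters
    ----------
    values : (nrows, ncols) float array, row 0 at the top
    xll, yll : lower-left corner of the grid (km)
    cell_size : cell side (km)
    nodata : no-data sentinel (default -9999)
    """

    values: np.ndarray
    xll: float
    yll: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        data = self.values[self.values != self.nodata]
        if data.size and (data.min() < 0 or data.max() > 1):
            raise ValueError("suitability values must lie in [0, 1] or equal nodata")

    @property
    def nrows(self):
        return self.values.shape[0]

    @property
    def ncols(self):
        return self.values.shape[1]

    @property
    def extent(self):
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cell_size,
            self.yll + self.nrows * self.cell_size,
        )

    def lookup(self, x, y):
        """Value of the cell containing each (x, y); nodata when outside the
        extent. Deterministic and total over the plane."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        y = np.atleast_1d(y)
        col = np.floor((x - self.xll) / self.cell_size).astype(int)
        row_up = np.floor((y - self.yll) / self.cell_size).astype(int)
        row = self.nrows - 1 - row_up
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        out = np.full(x.shape, self.nodata, dtype=float)
        out[ok] = self.values[row[ok], col[ok]]
        return float(out[0]) if scalar else out

    def lookup_or(self, x, y, fill=0.0):
        """Like `lookup` but no-data and out-of-extent become `fill`
        (uninhabitable by default)."""
        v = np.atleast_1d(self.lookup(x, y))
        v = np.where(v == self.nodata, fill, v)
        return v


def read_esri_ascii(path):
    """Read an ESRI ASCII grid (NCOLS/NROWS/XLLCORNER/YLLCORNER/CELLSIZE/
    NODATA_VALUE header, row-major values from the top row down)."""
    header = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].upper() in (
            "NCOLS",
            "NROWS",
            "XLLCORNER",
            "YLLCORNER",
            "CELLSIZE",
            "NODATA_VALUE",
        ):
            header[parts[0].upper()] = parts[1]
            data_start = i + 1
        else:
            break
    for key in ("NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE"):
        if key not in header:
            raise ValueError(f"ESRI ASCII header missing {key}")
    values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    nrows, ncols = int(header["NROWS"]), int(header["NCOLS"])
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    return SuitabilityRaster(
        values=values,
        xll=float(header["XLLCORNER"]),
        yll=float(header["YLLCORNER"]),
        cell_size=float(header["CELLSIZE"]),
        nodata=float(header.get("NODATA_VALUE", -9999.0)),
    )


def write_esri_ascii(raster, path):
    """Write an ESRI ASCII grid. Values use shortest-exact float formatting
    so read -> write -> read round-trips bit-exactly."""

    def fmt(v):
        return repr(int(v)) if float(v).is_integer() else repr(float(v))

    with open(path, "w") as fh:
        fh.write(f"NCOLS {raster.ncols}\n")
        fh.write(f"NROWS {raster.nrows}\n")
        fh.write(f"XLLCORNER {fmt(raster.xll)}\n")
        fh.write(f"YLLCORNER {fmt(raster.yll)}\n")
        fh.write(f"CELLSIZE {fmt(raster.cell_size)}\n")
        fh.write(f"NODATA_VALUE {fmt(raster.nodata)}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
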
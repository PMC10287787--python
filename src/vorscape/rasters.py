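"""Gridded raster containers and plain-text raster I/O.

Rasters are stored row-major with row index increasing downward (image
convention).  Cell-centre coordinates are ``x = (col + 0.5) * cell_size``
and ``y = (row + 0.5) * cell_size`` measured from the top-left corner.
Files use the ESRI ASCII grid format (``.asc``), a whitespace-delimited
text format readable by every mainstream GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CategoricalRaster",
    "ContinuousRaster",
    "AnalysisGrid",
    "ZoneMap",
    "write_ascii_grid",
    "read_ascii_grid",
]


@dataclass
class CategoricalRaster:
    """Integer-coded land-use raster.

    Parameters
    ----------
    values
        2-D integer array of class codes.  ``nodata_code`` marks cells
        outside the study area; valid codes are positive integers.
    cell_size
        Edge length of one cell, in map units (e.g. km).
    nodata_code
        Code treated as missing.  Default 0.
    """

    values: np.ndarray
    cell_size: float = 1.0
    nodata_code: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("categorical raster requires an integer dtype")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def classes(self) -> np.ndarray:
        """Sorted class codes present, excluding nodata."""
        u = np.unique(self.values)
        return u[u != self.nodata_code]

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata_code


@dataclass
class ContinuousRaster:
    """Single-band float raster (NDVI, temperature, precipitation...).

    Missing cells are NaN.
    """

    values: np.ndarray
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class AnalysisGrid:
    """Tiling of a raster into square evaluation windows.

    Every cell belongs to exactly one tile; tiles on the right/bottom
    edge may be smaller than ``window_size`` when the raster dimensions
    are not multiples of it.
    """

    def __init__(self, nrows: int, ncols: int, window_size: int, cell_size: float = 1.0):
        if window_size < 2:
            raise ValueError("window_size must be >= 2")
        if nrows < 1 or ncols < 1:
            raise ValueError("raster dimensions must be positive")
        self.nrows = nrows
        self.ncols = ncols
        self.window_size = window_size
        self.cell_size = cell_size
        self.n_tile_rows = int(np.ceil(nrows / window_size))
        self.n_tile_cols = int(np.ceil(ncols / window_size))

    @classmethod
    def for_raster(cls, raster, window_size: int) -> "AnalysisGrid":
        nr, nc = raster.shape
        return cls(nr, nc, window_size, raster.cell_size)

    @property
    def n_tiles(self) -> int:
        return self.n_tile_rows * self.n_tile_cols

    def tile_slices(self, tile_row: int, tile_col: int) -> tuple[slice, slice]:
        ws = self.window_size
        r0, c0 = tile_row * ws, tile_col * ws
        return slice(r0, min(r0 + ws, self.nrows)), slice(c0, min(c0 + ws, self.ncols))

    def iter_tiles(self):
        """Yield ``(tile_row, tile_col, row_slice, col_slice)`` in row-major order."""
        for tr in range(self.n_tile_rows):
            for tc in range(self.n_tile_cols):
                rs, cs = self.tile_slices(tr, tc)
                yield tr, tc, rs, cs

    def tile_centres(self) -> np.ndarray:
        """(n_tiles, 2) array of tile-centre (x, y) coordinates, row-major order."""
        out = np.empty((self.n_tiles, 2))
        k = 0
        for _, _, rs, cs in self.iter_tiles():
            out[k, 0] = 0.5 * (cs.start + cs.stop) * self.cell_size
            out[k, 1] = 0.5 * (rs.start + rs.stop) * self.cell_size
            k += 1
        return out


@dataclass
class ZoneMap:
    """Partition of the grid into contiguous zones (county analogue)."""

    zone_ids: np.ndarray  # 2-D int array, zones numbered 1..n_zones
    cell_size: float = 1.0
    centroids: np.ndarray = field(default=None)  # (n_zones, 2) x,y

    def __post_init__(self) -> None:
        self.zone_ids = np.asarray(self.zone_ids)
        if self.centroids is None:
            self.centroids = self._compute_centroids()
        else:
            self.centroids = np.asarray(self.centroids, dtype=float)

    @property
    def n_zones(self) -> int:
        return int(self.zone_ids.max())

    def _compute_centroids(self) -> np.ndarray:
        nz = int(self.zone_ids.max())
        rows, cols = np.indices(self.zone_ids.shape)
        x = (cols + 0.5) * self.cell_size
        y = (rows + 0.5) * self.cell_size
        flat = self.zone_ids.ravel()
        counts = np.bincount(flat, minlength=nz + 1)[1:]
        cx = np.bincount(flat, weights=x.ravel(), minlength=nz + 1)[1:] / counts
        cy = np.bincount(flat, weights=y.ravel(), minlength=nz + 1)[1:] / counts
        return np.column_stack([cx, cy])


def write_ascii_grid(path, raster, nodata_value: float | int | None = None) -> None:
    """Write a raster to an ESRI ASCII grid file.

    Categorical rasters are written as integers with their nodata code;
    continuous rasters as floats with NaN mapped to ``nodata_value``
    (default -9999).
    """
    path = Path(path)
    vals = raster.values
    categorical = np.issubdtype(vals.dtype, np.integer)
    if nodata_value is None:
        nodata_value = raster.nodata_code if categorical else -9999.0
    nr, nc = vals.shape
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {nodata_value}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        if categorical:
            np.savetxt(fh, vals, fmt="%d")
        else:
            out = np.where(np.isnan(vals), nodata_value, vals)
            np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path, categorical: bool = False):
    """Read an ESRI ASCII grid; returns CategoricalRaster or ContinuousRaster."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    cell = header.get("cellsize", 1.0)
    nodata = header.get("nodata_value", -9999.0)
    if categorical:
        return CategoricalRaster(data.astype(int), cell_size=cell, nodata_code=int(nodata))
    vals = data.astype(float)
    vals[vals == nodata] = np.nan
    return ContinuousRaster(vals, cell_size=cell)
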
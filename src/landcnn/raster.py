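"""Gridded landscape rasters.

A :class:`RasterGrid` is the minimal georeferenced container the pipeline
needs: a rectangular array of non-negative cell values (a landscape predictor
or a composite resistance surface), a boolean nodata mask, a cell size and the
map coordinates of the lower-left corner.  Rasters are persisted as ESRI ASCII
grids, a plain-text interchange format understood by every GIS stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

_ASCII_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band raster.

    ``values`` is indexed ``[row, col]`` with row 0 at the *top* of the map
    (raster convention); ``origin`` is the map coordinate of the lower-left
    corner of the lower-left cell.  ``cell_size`` is the side length of a
    square cell in map units.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # True where nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("raster must be at least 2x2")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("raster has non-finite values on unmasked cells")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of a cell center."""
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a map coordinate."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - self.origin[1]) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"coordinate ({x}, {y}) outside raster extent")
        return row, col

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy(),
        )


def write_ascii_grid(raster: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    path = Path(path)
    vals = raster.values.copy()
    vals[raster.nodata_mask] = _ASCII_NODATA
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin[0]:.10g}\n"
        f"yllcorner {raster.origin[1]:.10g}\n"
        f"cellsize {raster.cell_size:.10g}\n"
        f"NODATA_value {_ASCII_NODATA:g}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _ASCII_NODATA)
    mask = np.isclose(values, nodata)
    values = values.copy()
    values[mask] = 0.0
    return RasterGrid(
        values=values,
        cell_size=header.get("cellsize", 1.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata_mask=mask,
    )
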
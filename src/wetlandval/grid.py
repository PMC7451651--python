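"""Regular square-cell grid geometry and ESRI ASCII raster I/O.

All grids in this package are axis-aligned with square cells. ``origin``
is the *top-left corner* of the top-left cell; row index increases
southwards (map convention), column index eastwards. The on-disk format
is the plain-text ESRI ASCII grid (``ncols/nrows/xllcorner/yllcorner/
cellsize/NODATA_value`` header followed by rows from north to south),
which any GIS reads directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: top-left origin, square cell size, shape."""

    origin_x: float
    origin_y: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must be at least 1x1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area(self) -> float:
        """Cell area in squared map units (m^2 for metric grids)."""
        return self.cell_size * self.cell_size

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of all cell centers, each of shape (nrows, ncols)."""
        return np.meshgrid(self.x_centers, self.y_centers)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.cell_size,
            self.origin_x + self.ncols * self.cell_size,
            self.origin_y,
        )

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
        )


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid.

    Returns ``(values, grid, nodata)`` with values as float64 (cast to int
    by callers that know the band is categorical). Both ``xllcorner`` and
    ``xllcenter`` header variants are accepted.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, dtype=np.float64, ndmin=2)

    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required ASCII-grid header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cs = header["cellsize"]
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-center registration
        xll, yll = header["xllcenter"] - cs / 2, header["yllcenter"] - cs / 2
    nodata = header.get("nodata_value", -9999.0)
    grid = GridSpec(origin_x=xll, origin_y=yll + nrows * cs, cell_size=cs,
                    nrows=nrows, ncols=ncols)
    return values, grid, nodata


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    nodata: float = -9999,
    fmt: str = "%.6g",
) -> None:
    """Write an ESRI ASCII grid (integer fmt e.g. ``"%d"`` for categorical bands)."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    xmin, ymin, _, _ = grid.bounds
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_x:.6f}\n")
        fh.write(f"yllcorner {ymin:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {fmt % nodata}\n")
        np.savetxt(fh, values, fmt=fmt)
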
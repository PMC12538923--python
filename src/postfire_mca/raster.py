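"""Minimal georeferenced raster container and plain-text grid I/O.

Rasters are square-celled, north-up grids in a projected (metric)
coordinate system.  Nodata is represented as ``numpy.nan`` in memory and
as the ``NODATA_value`` sentinel in the on-disk ESRI ASCII grid format
(``.asc``), which any desktop GIS reads directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import GridAlignmentError, GridShapeError

_GEO_TOL = 1e-6


@dataclass
class Raster:
    """A 2-D grid with an origin at its north-west corner.

    Parameters
    ----------
    data:
        2-D float array; ``nan`` marks nodata.
    west, north:
        Map coordinates of the outer corner of the top-left cell.
    cellsize:
        Cell edge length in map units (metres).
    crs:
        Free-text coordinate-system label (fixtures use a local metric CRS).
    """

    data: np.ndarray
    west: float
    north: float
    cellsize: float
    crs: str = "LOCAL_METRIC"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise GridShapeError(f"raster data must be 2-D, got {self.data.ndim}-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.cellsize

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.cellsize

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north)."""
        return (self.west, self.south, self.east, self.north)

    def x_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.shape[1]) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.shape[0]) + 0.5) * self.cellsize

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of cell-center coordinates."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def like(self, data: np.ndarray) -> "Raster":
        """New raster with the same georeferencing and the given data."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise GridShapeError(
                f"data shape {data.shape} != raster shape {self.shape}"
            )
        return replace(self, data=data)

    def copy(self) -> "Raster":
        return replace(self, data=self.data.copy())

    def same_grid(self, other: "Raster", tol: float = _GEO_TOL) -> bool:
        return (
            self.shape == other.shape
            and abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def require_same_grid(self, other: "Raster") -> None:
        if self.shape != other.shape:
            raise GridShapeError(f"shapes differ: {self.shape} vs {other.shape}")
        if not self.same_grid(other):
            raise GridAlignmentError("grids are not co-registered")


def read_ascii_grid(path: str | Path, crs: str = "LOCAL_METRIC") -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    data = np.vstack(rows)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise GridShapeError(
            f"{path}: body shape {data.shape} != header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    cellsize = header["cellsize"]
    return Raster(
        data=data,
        west=header["xllcorner"],
        north=header["yllcorner"] + nrows * cellsize,
        cellsize=cellsize,
        crs=crs,
    )


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0) -> Path:
    """Write an ESRI ASCII grid (.asc).  Deterministic formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nrows, ncols = raster.shape
    out = np.where(np.isfinite(raster.data), raster.data, nodata)
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.west:.6f}\n")
        fh.write(f"yllcorner {raster.south:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")
    return path
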
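"""Minimal raster container and ESRI ASCII grid I/O.

Rasters are 2-D float64 arrays in row-major, north-up orientation
(row 0 is the northernmost row).  NoData is represented as NaN in
memory and as the ``NODATA_value`` sentinel on disk.  Geometry is a
lower-left origin plus a square cell size, which is exactly what the
ASCII grid header carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii", "write_ascii"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster: data array plus grid geometry.

    Parameters
    ----------
    data:
        2-D array; NaN marks NoData cells.
    cell_size:
        Edge length of a (square) cell, in map units.
    origin:
        (x, y) of the lower-left corner of the grid.
    """

    data: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        return np.isfinite(self.data)

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, data: np.ndarray) -> "Raster":
        """New raster with the same geometry but different data."""
        if data.shape != self.shape:
            raise ValueError(f"shape mismatch: {data.shape} vs {self.shape}")
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def write(self, path: str | Path) -> None:
        write_ascii(self, path)


def require_aligned(*rasters: Raster) -> None:
    """Raise if any pair of rasters disagrees on geometry."""
    ref = rasters[0]
    for r in rasters[1:]:
        if not ref.same_geometry(r):
            raise ValueError(
                f"raster geometry mismatch: {ref.shape}/{ref.cell_size}/{ref.origin}"
                f" vs {r.shape}/{r.cell_size}/{r.origin}"
            )


def write_ascii(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc) with a NODATA_value sentinel."""
    nrows, ncols = raster.shape
    x0, y0 = raster.origin
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {y0:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {_NODATA:.1f}\n"
    )
    body = np.where(raster.valid, raster.data, _NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value", "xllcenter", "yllcenter"}:
                meta[key] = float(value)
                pos = fh.tell()
            else:  # headerless tail reached early
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    nodata = meta.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    cell = meta.get("cellsize", 1.0)
    # centre-registered headers shift by half a cell
    x0 = meta.get("xllcorner", meta.get("xllcenter", 0.0) - cell / 2 if "xllcenter" in meta else 0.0)
    y0 = meta.get("yllcorner", meta.get("yllcenter", 0.0) - cell / 2 if "yllcenter" in meta else 0.0)
    if "nrows" in meta and data.shape[0] != int(meta["nrows"]):
        raise ValueError("row count does not match header")
    if "ncols" in meta and data.shape[1] != int(meta["ncols"]):
        raise ValueError("column count does not match header")
    return Raster(data=data, cell_size=cell, origin=(x0, y0))
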
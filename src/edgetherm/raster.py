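"""Minimal single-band raster container and text (ESRI ASCII grid) I/O.

All grids are north-up on a flat local coordinate frame in metres: row 0 is
the northernmost row, the origin is the *outer* corner of the upper-left
pixel (pixel-is-area convention), and the value reserved for missing data is
-9999 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class RasterGrid:
    """A 2-D field (canopy %, temperature, elevation, cloud flag, distance).

    Parameters
    ----------
    values : ndarray
        2-D array; ``values[0, 0]`` is the upper-left (north-west) pixel.
    origin : (float, float)
        (x0, y0) of the upper-left pixel's outer corner, metres.
    pixel_size : float
        Pixel edge length in metres (square pixels).
    nodata : float
        Sentinel marking missing values.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 30.0
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must form a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate vectors (xs, ys) of pixel centers, metres.

        ``xs[j]`` is the x of column j (increasing east), ``ys[i]`` the y of
        row i (decreasing southward from the origin).
        """
        x0, y0 = self.origin
        nrows, ncols = self.values.shape
        xs = x0 + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.pixel_size
        return xs, ys

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        return RasterGrid(values, origin=self.origin,
                          pixel_size=self.pixel_size, nodata=self.nodata)


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write a grid as an ESRI ASCII raster (plain text, row 0 = north)."""
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    yll = y0 - nrows * grid.pixel_size
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.pixel_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, grid.values, fmt="%.10g")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"grid body {values.shape} does not match header ({nrows}, {ncols})")
    cell = header["cellsize"]
    y0 = header["yllcorner"] + nrows * cell
    return RasterGrid(values, origin=(header["xllcorner"], y0),
                      pixel_size=cell, nodata=header["nodata_value"])
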
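"""Georeferenced raster lattice: the in-memory container every stage shares.

A :class:`RasterGrid` is a 2-D array of values on a regular lattice in an
unprojected geographic coordinate system (degrees).  Row 0 is the
northernmost row; ``(x_origin, y_origin)`` is the upper-left *corner* of the
upper-left cell.  In memory, missing values are ``NaN``; on disk they are the
``nodata`` sentinel of the ESRI ASCII grid format, which is the single-band
text raster format this package reads and writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: kilometres per degree of latitude (spherical mean radius convention)
KM_PER_DEG = 111.3195

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    data: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edges, degrees."""
        nrows, ncols = self.shape
        return (
            self.x_origin,
            self.y_origin - nrows * self.cell_size,
            self.x_origin + ncols * self.cell_size,
            self.y_origin,
        )

    def lon_centers(self) -> np.ndarray:
        ncols = self.shape[1]
        return self.x_origin + (np.arange(ncols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        nrows = self.shape[0]
        return self.y_origin - (np.arange(nrows) + 0.5) * self.cell_size

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        """True if the two rasters share shape, origin and cell size."""
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def copy_with(self, data: np.ndarray) -> "RasterGrid":
        """New raster on this grid carrying different values."""
        return replace(self, data=np.asarray(data))

    # -- values ------------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        d = self.data
        if np.issubdtype(d.dtype, np.floating):
            return np.isfinite(d)
        return np.ones(d.shape, dtype=bool)

    def pixel_areas_km2(self) -> np.ndarray:
        """Per-pixel surface area in km², varying with latitude (planar
        approximation on the sphere, constant along each row)."""
        lat = np.deg2rad(self.lat_centers())
        row_area = (self.cell_size * KM_PER_DEG) ** 2 * np.cos(lat)
        return np.broadcast_to(row_area[:, None], self.shape).copy()

    # -- I/O ---------------------------------------------------------------
    def write_ascii(self, path) -> None:
        nrows, ncols = self.shape
        yll = self.y_origin - nrows * self.cell_size
        data = np.asarray(self.data, dtype=float)
        out = np.where(np.isfinite(data), data, self.nodata)
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.x_origin:.12g}\n")
            fh.write(f"yllcorner {yll:.12g}\n")
            fh.write(f"cellsize {self.cell_size:.12g}\n")
            fh.write(f"NODATA_value {self.nodata:.12g}\n")
            np.savetxt(fh, out, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                header[key.lower()] = float(value)
            data = np.loadtxt(fh, ndmin=2)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        if data.shape != (nrows, ncols):
            raise ValueError(
                f"ASCII grid body shape {data.shape} does not match header "
                f"({nrows}, {ncols})"
            )
        nodata = header.get("nodata_value", DEFAULT_NODATA)
        data = np.where(data == nodata, np.nan, data)
        cell = header["cellsize"]
        return cls(
            data=data,
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"] + nrows * cell,
            cell_size=cell,
            nodata=nodata,
        )
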
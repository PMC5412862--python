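"""Aggregate geolocated point events onto a fixed geographic grid.

Events are binned by flooring each coordinate to the cell size — the cell
containing an event at ``(lon, lat)`` has origin ``(floor(lon/c)*c,
floor(lat/c)*c)``.  Floor means toward minus infinity on both axes: at
southern latitudes truncation toward zero would merge the two cell rows
straddling the equator, floor keeps the partition consistent.  Cells are
half-open ``[origin, origin + c)``, so every event belongs to exactly one
cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RasterGrid

logger = logging.getLogger(__name__)


@dataclass
class GridExtent:
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("extent must be non-degenerate")


def read_events_csv(path) -> pd.DataFrame:
    """Read a `lon,lat[,timestamp]` CSV, dropping malformed rows with a
    logged count."""
    df = pd.read_csv(path)
    if not {"lon", "lat"}.issubset(df.columns):
        raise ValueError("events CSV must have 'lon' and 'lat' columns")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        lon.notna()
        & lat.notna()
        & lon.between(-180, 180)
        & lat.between(-90, 90)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("rejected %d malformed event rows", dropped)
    out = df.loc[ok].copy()
    out["lon"] = lon[ok]
    out["lat"] = lat[ok]
    return out.reset_index(drop=True)


def aggregate_points(
    events: pd.DataFrame,
    cell_size: float,
    extent: GridExtent | tuple[float, float, float, float],
) -> tuple[RasterGrid, int]:
    """Bin events into a count grid anchored at integer multiples of
    ``cell_size``.

    Returns the count raster and the number of events dropped for lying
    outside the extent.  The grid sum always equals the number of in-extent
    events.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if not isinstance(extent, GridExtent):
        extent = GridExtent(*extent)

    # anchor the lattice at multiples of cell_size covering the extent
    c = cell_size
    col0 = int(np.floor(extent.xmin / c))
    row_hi = int(np.ceil(extent.ymax / c))  # top edge index (exclusive)
    ncols = int(np.ceil(extent.xmax / c)) - col0
    nrows = row_hi - int(np.floor(extent.ymin / c))

    counts = np.zeros((nrows, ncols), dtype=np.int64)
    lon = np.asarray(events["lon"], dtype=float) if len(events) else np.array([])
    lat = np.asarray(events["lat"], dtype=float) if len(events) else np.array([])
    inside = (
        (lon >= extent.xmin)
        & (lon < extent.xmax)
        & (lat >= extent.ymin)
        & (lat < extent.ymax)
    )
    n_dropped = int(len(lon) - inside.sum())
    if n_dropped:
        logger.warning("dropped %d events outside the extent", n_dropped)

    if inside.any():
        ix = np.floor(lon[inside] / c).astype(np.int64) - col0
        iy = row_hi - 1 - np.floor(lat[inside] / c).astype(np.int64)
        np.add.at(counts, (iy, ix), 1)

    grid = RasterGrid(
        counts, x_origin=col0 * c, y_origin=row_hi * c, cell_size=c
    )
    return grid, n_dropped


def align_to_grid(count_grid: RasterGrid, target: RasterGrid) -> RasterGrid:
    """Resample a count raster onto the target lattice.

    Aggregation (target cells coarser than or equal to source cells) assigns
    each source cell to the target cell containing its center and sums, so
    total count is conserved.  Refinement (target finer) gives each target
    cell the value of the source cell containing its center.  Disjoint
    extents are an error.
    """
    sxmin, symin, sxmax, symax = count_grid.extent
    txmin, tymin, txmax, tymax = target.extent
    if sxmax <= txmin or txmax <= sxmin or symax <= tymin or tymax <= symin:
        raise ValueError("source and target extents are disjoint")

    if count_grid.same_grid(target):
        return target.copy_with(np.asarray(count_grid.data, dtype=float))

    tn, tm = target.shape
    out = np.zeros((tn, tm), dtype=float)
    c_t = target.cell_size

    if target.cell_size >= count_grid.cell_size - 1e-12:
        # sum-preserving aggregation by source-cell centers
        sr, sc = count_grid.shape
        lon_c = count_grid.lon_centers()
        lat_c = count_grid.lat_centers()
        jj = np.floor((lon_c - target.x_origin) / c_t).astype(np.int64)
        ii = np.floor((target.y_origin - lat_c) / c_t).astype(np.int64)
        ok_j = (jj >= 0) & (jj < tm)
        ok_i = (ii >= 0) & (ii < tn)
        data = np.asarray(count_grid.data, dtype=float)
        block = data[np.ix_(ok_i, ok_j)]
        np.add.at(out, (ii[ok_i][:, None], jj[ok_j][None, :]), block)
    else:
        # nearest-value refinement by target-cell centers
        lon_t = target.lon_centers()
        lat_t = target.lat_centers()
        c_s = count_grid.cell_size
        jj = np.floor((lon_t - count_grid.x_origin) / c_s).astype(np.int64)
        ii = np.floor((count_grid.y_origin - lat_t) / c_s).astype(np.int64)
        ok_j = (jj >= 0) & (jj < count_grid.shape[1])
        ok_i = (ii >= 0) & (ii < count_grid.shape[0])
        data = np.asarray(count_grid.data, dtype=float)
        out[np.ix_(ok_i, ok_j)] = data[np.ix_(ii[ok_i], jj[ok_j])]

    return target.copy_with(out)
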
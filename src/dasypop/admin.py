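"""Administrative census layers as pixel partitions of the raster lattice.

Internally an :class:`AdminLayer` is a label raster (``-1`` outside the study
region, otherwise the integer row index into ``units``) plus a unit table
with identifier, parent identifier, population count and surface area.
Polygon export derives unit boundaries from pixel membership, so zonal
arithmetic against any co-registered raster is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grids import RasterGrid

UNIT_COLUMNS = ["unit_id", "parent_id", "pop_count", "area_km2"]


@dataclass
class AdminLayer:
    labels: np.ndarray  # int array, -1 = outside region
    units: pd.DataFrame  # row i describes label i; columns UNIT_COLUMNS
    x_origin: float
    y_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        missing = [c for c in UNIT_COLUMNS if c not in self.units.columns]
        if missing:
            raise ValueError(f"unit table missing columns: {missing}")
        n = len(self.units)
        inside = self.labels[self.labels >= 0]
        if inside.size and inside.max() >= n:
            raise ValueError("label raster references units beyond the table")
        if self.units["unit_id"].duplicated().any():
            raise ValueError("unit ids must be unique")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def grid_like(self) -> RasterGrid:
        """Empty float raster on this layer's lattice."""
        return RasterGrid(
            np.full(self.labels.shape, np.nan),
            self.x_origin,
            self.y_origin,
            self.cell_size,
        )

    def pixel_counts(self) -> np.ndarray:
        inside = self.labels[self.labels >= 0]
        return np.bincount(inside, minlength=self.n_units)

    def zonal_sum(self, raster: RasterGrid) -> np.ndarray:
        """Sum of raster values over each unit's pixels (NaN excluded)."""
        if raster.shape != self.labels.shape:
            raise ValueError("raster shape does not match admin layer")
        lab = self.labels.ravel()
        val = np.asarray(raster.data, dtype=float).ravel()
        ok = (lab >= 0) & np.isfinite(val)
        return np.bincount(lab[ok], weights=val[ok], minlength=self.n_units)

    def with_counts(self, counts: np.ndarray) -> "AdminLayer":
        units = self.units.copy()
        units["pop_count"] = np.asarray(counts, dtype=np.int64)
        return replace(self, units=units)

    # -- export ------------------------------------------------------------
    def unit_polygon(self, label: int):
        rows, cols = np.nonzero(self.labels == label)
        cs = self.cell_size
        cells = [
            box(
                self.x_origin + c * cs,
                self.y_origin - (r + 1) * cs,
                self.x_origin + (c + 1) * cs,
                self.y_origin - r * cs,
            )
            for r, c in zip(rows, cols)
        ]
        return unary_union(cells)

    def to_geojson(self, path) -> None:
        features = []
        for i, row in self.units.iterrows():
            geom = self.unit_polygon(int(i))
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "unit_id": row["unit_id"],
                        "parent_id": row["parent_id"],
                        "pop_count": int(row["pop_count"]),
                        "area_km2": float(row["area_km2"]),
                    },
                    "geometry": mapping(shapely.set_precision(geom, 1e-9)),
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def admin_from_geojson(path, descriptor: RasterGrid) -> AdminLayer:
    """Rasterize a GeoJSON admin layer onto a grid descriptor.

    Each pixel is assigned to the unit whose polygon covers the pixel
    center; boundary ties go to the lowest unit_id (features are scanned in
    unit_id order and the first match wins).
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = sorted(
        doc["features"], key=lambda f: f["properties"]["unit_id"]
    )
    lon = descriptor.lon_centers()
    lat = descriptor.lat_centers()
    xx, yy = np.meshgrid(lon, lat)
    labels = np.full(descriptor.shape, -1, dtype=np.int32)
    rows = []
    for i, feat in enumerate(feats):
        geom = shapely.geometry.shape(feat["geometry"])
        hit = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(
            descriptor.shape
        )
        # boundary centers: contains misses them; buffer a hair outward
        if not hit.any():
            hit = shapely.contains_xy(
                geom.buffer(descriptor.cell_size * 1e-6),
                xx.ravel(), yy.ravel(),
            ).reshape(descriptor.shape)
        labels[(labels == -1) & hit] = i
        p = feat["properties"]
        rows.append(
            (p["unit_id"], p.get("parent_id", ""), int(p.get("pop_count", 0)),
             float(p.get("area_km2", 0.0)))
        )
    units = pd.DataFrame(rows, columns=UNIT_COLUMNS)
    return AdminLayer(
        labels, units, descriptor.x_origin, descriptor.y_origin,
        descriptor.cell_size,
    )


def check_nesting(coarse: AdminLayer, fine: AdminLayer) -> None:
    """Raise if fine units do not nest exactly inside their coarse parents
    or if the two levels' total counts disagree."""
    parent_of = coarse.units.reset_index().set_index("unit_id")["index"]
    fine_parent_label = fine.units["parent_id"].map(parent_of).to_numpy()
    mapped = np.full_like(fine.labels, -1)
    inside = fine.labels >= 0
    mapped[inside] = fine_parent_label[fine.labels[inside]]
    if not np.array_equal(mapped, coarse.labels):
        raise ValueError("fine units do not nest inside coarse units")
    fine_sums = (
        fine.units.groupby("parent_id")["pop_count"].sum().reindex(
            coarse.units["unit_id"]
        )
    )
    if not np.array_equal(
        fine_sums.to_numpy(), coarse.units["pop_count"].to_numpy()
    ):
        raise ValueError("fine counts do not sum to coarse counts")
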
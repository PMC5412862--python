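"""Cross-scale accuracy assessment of disaggregated population grids.

The validation design: train the model on coarse census units, redistribute
their counts to pixels, aggregate the pixel map back up to the *finer*
census level held in reserve, and compare with the fine counts.  Error
summaries are RMSE, RMSE as a percentage of the mean observed unit count
(%RMSE), and MAE; paired model variants (with / without an extra covariate)
are compared by differencing their reports, positive difference meaning the
added covariate improved accuracy.

Also provides the average spatial resolution (ASR) statistic — the square
root of total surface area over the number of administrative units, a mean
unit-size summary in km — and per-pixel / per-unit difference maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admin import AdminLayer
from .grids import RasterGrid

logger = logging.getLogger(__name__)


def aggregate_to_units(
    pop: RasterGrid, admin_fine: AdminLayer
) -> pd.Series:
    """Zonal sum of a population grid over fine units (predicted counts)."""
    if pop.shape != admin_fine.labels.shape:
        raise ValueError("population grid does not match admin layer")
    empty = admin_fine.pixel_counts() == 0
    sums = admin_fine.zonal_sum(pop)
    out = pd.Series(sums, index=admin_fine.units["unit_id"], name="pred")
    if empty.any():
        dropped = admin_fine.units.loc[empty, "unit_id"].tolist()
        logger.warning("dropping %d fine units with zero pixels: %s",
                       len(dropped), dropped)
        out = out[~empty]
    return out


@dataclass
class AccuracyReport:
    label: str
    rmse: float
    pct_rmse: float
    mae: float
    n_units: int
    mean_obs: float

    def to_row(self) -> dict:
        return {
            "model": self.label,
            "rmse": round(self.rmse, 2),
            "pct_rmse": round(self.pct_rmse, 2),
            "mae": round(self.mae, 2),
            "n_units": self.n_units,
        }


def accuracy(
    pred: pd.Series, obs: pd.Series, label: str = ""
) -> AccuracyReport:
    """RMSE, %RMSE and MAE of predicted versus observed unit counts.

    ``pred`` and ``obs`` are indexed by unit id and must match exactly;
    %RMSE uses the mean of the observed counts over the compared units.
    """
    pred, obs = pd.Series(pred), pd.Series(obs)
    extra = pred.index.difference(obs.index)
    missing = obs.index.difference(pred.index)
    if len(extra) or len(missing):
        raise ValueError(
            f"unit id mismatch: {len(extra)} unmatched predictions "
            f"{list(extra[:5])}, {len(missing)} unmatched observations "
            f"{list(missing[:5])}"
        )
    if len(obs) < 1:
        raise ValueError("need at least one unit")
    obs = obs.astype(float)
    pred = pred.reindex(obs.index).astype(float)
    mean_obs = float(obs.mean())
    if mean_obs <= 0:
        raise ValueError("mean observed count must be positive")
    err = pred.to_numpy() - obs.to_numpy()
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    return AccuracyReport(
        label=label,
        rmse=rmse,
        pct_rmse=100.0 * rmse / mean_obs,
        mae=mae,
        n_units=len(obs),
        mean_obs=mean_obs,
    )


@dataclass
class ComparisonReport:
    """Paired difference between two model variants, reported as
    (without − with): positive numbers mean the added covariate helped."""

    report_without: AccuracyReport
    report_with: AccuracyReport

    @property
    def d_rmse(self) -> float:
        return self.report_without.rmse - self.report_with.rmse

    @property
    def d_pct_rmse(self) -> float:
        return self.report_without.pct_rmse - self.report_with.pct_rmse

    @property
    def d_mae(self) -> float:
        return self.report_without.mae - self.report_with.mae

    def to_frame(self) -> pd.DataFrame:
        rows = [
            self.report_without.to_row(),
            self.report_with.to_row(),
            {
                "model": "difference (without - with)",
                "rmse": round(self.d_rmse, 2),
                "pct_rmse": round(self.d_pct_rmse, 2),
                "mae": round(self.d_mae, 2),
                "n_units": self.report_without.n_units,
            },
        ]
        return pd.DataFrame(rows)


def compare(
    report_without: AccuracyReport, report_with: AccuracyReport
) -> ComparisonReport:
    return ComparisonReport(report_without, report_with)


def asr(total_area_km2: float, n_units: int) -> float:
    """Average spatial resolution: sqrt(area / number of units), in km."""
    if total_area_km2 <= 0 or n_units <= 0:
        raise ValueError("area and unit count must be positive")
    return math.sqrt(total_area_km2 / n_units)


def difference_map(pop_a: RasterGrid, pop_b: RasterGrid) -> RasterGrid:
    """Per-pixel ``a − b``; nodata where either input is nodata."""
    if not pop_a.same_grid(pop_b):
        raise ValueError("grids do not share a descriptor")
    a = np.asarray(pop_a.data, dtype=float)
    b = np.asarray(pop_b.data, dtype=float)
    out = a - b
    out[~(np.isfinite(a) & np.isfinite(b))] = np.nan
    return pop_a.copy_with(out)


def unit_error_map(
    pred: pd.Series, obs: pd.Series, admin_fine: AdminLayer
) -> tuple[pd.Series, RasterGrid]:
    """Signed per-unit error (predicted − observed) and its raster
    rendering, each unit's pixels carrying the unit's error."""
    pred, obs = pd.Series(pred), pd.Series(obs)
    err = (pred.reindex(obs.index) - obs).rename("error")
    per_label = (
        err.reindex(admin_fine.units["unit_id"]).to_numpy(dtype=float)
    )
    out = np.full(admin_fine.labels.shape, np.nan)
    inside = admin_fine.labels >= 0
    out[inside] = per_label[admin_fine.labels[inside]]
    return err, admin_fine.grid_like().copy_with(out)
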
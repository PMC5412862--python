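"""Random-forest dasymetric core.

The estimation chain: summarize covariates over census units
(:func:`zonal_summarize`), regress unit population density on the summaries
with a random forest (:func:`fit_forest`), predict a per-pixel density
weighting layer (:func:`predict_weights`), and redistribute unit census
counts over pixels proportionally to the weights
(:func:`dasymetric_redistribute`), which preserves every unit's count
exactly up to floating-point error.

The forest is trained on log-transformed densities by default (zero-density
units are excluded from training, as they have no log-density); predictions
are back-transformed with ``exp``.  Out-of-bag variance explained and
permutation importances — the mean increase in OOB mean squared error when
one covariate is permuted and OOB predictions recomputed, tree by tree —
are computed here on the per-tree bootstrap structure rather than taken
from any library's aggregate metric, so the quantity is defined by this
module's contract and testable against it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .admin import AdminLayer
from .covariates import CovariateStack
from .grids import RasterGrid

logger = logging.getLogger(__name__)

#: ZonalTable columns that are never treated as covariates
RESERVED_COLUMNS = {"unit_id", "parent_id", "pop_count", "area_km2", "density"}


def zonal_summarize(stack: CovariateStack, admin: AdminLayer) -> pd.DataFrame:
    """Per-unit covariate means and population density.

    Each covariate is averaged over the unit's pixels, excluding nodata
    pixels of that layer.  Units with zero valid pixels for any layer are
    dropped with a warning.  Density is persons per km² from the unit's
    count and area.
    """
    if admin.n_units == 0:
        raise ValueError("empty admin layer")
    if stack.descriptor.shape != admin.labels.shape:
        raise ValueError("stack grid does not match admin layer")
    lab = admin.labels.ravel()
    inside = lab >= 0
    n = admin.n_units

    table = admin.units[["unit_id", "pop_count", "area_km2"]].copy()
    keep = np.ones(n, dtype=bool)
    for name, layer in stack.layers.items():
        val = np.asarray(layer.data, dtype=float).ravel()
        ok = inside & np.isfinite(val)
        sums = np.bincount(lab[ok], weights=val[ok], minlength=n)
        cnts = np.bincount(lab[ok], minlength=n)
        with np.errstate(invalid="ignore"):
            table[name] = sums / cnts
        keep &= cnts > 0
    keep &= table["area_km2"].to_numpy() > 0
    if not keep.all():
        dropped = table.loc[~keep, "unit_id"].tolist()
        logger.warning("dropping %d units with no valid pixels: %s",
                       len(dropped), dropped)
    table = table.loc[keep].reset_index(drop=True)
    table["density"] = table["pop_count"] / table["area_km2"]
    return table


@dataclass
class ForestFit:
    """A fitted density forest plus its OOB diagnostics."""

    model: RandomForestRegressor
    covariates: list[str]
    transform: str  # "log" | "identity"
    oob_var_explained: float
    importances: pd.Series  # increase in OOB MSE under permutation
    n_units: int
    fingerprint: str


def _transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log":
        return np.log(y)
    if transform == "identity":
        return y
    raise ValueError(f"unknown transform {transform!r}")


def _back_transform(y: np.ndarray, transform: str) -> np.ndarray:
    return np.exp(y) if transform == "log" else y


def _oob_importances(
    model: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation importance on per-tree OOB samples.

    For each tree: take its out-of-bag rows, record the tree's OOB MSE,
    permute one covariate among those rows, re-predict, and record the MSE
    increase; average increases over trees.
    """
    n = len(y)
    n_features = X.shape[1]
    increases = np.zeros((len(model.estimators_), n_features))
    counted = np.zeros(len(model.estimators_), dtype=bool)
    for t, (tree, sample_idx) in enumerate(
        zip(model.estimators_, model.estimators_samples_)
    ):
        oob = np.ones(n, dtype=bool)
        oob[sample_idx] = False
        if not oob.any():
            continue
        counted[t] = True
        Xo, yo = X[oob], y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        for j in range(n_features):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xo)), j]
            increases[t, j] = np.mean((tree.predict(Xp) - yo) ** 2) - base
    if not counted.any():
        return np.zeros(n_features)
    return increases[counted].mean(axis=0)


def fit_forest(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
    transform: str = "log",
) -> ForestFit:
    """Fit the density-weighting forest on a zonal table.

    Unpruned regression trees, one-third of the covariates tried per split,
    bootstrap resampling; deterministic given ``seed``.
    """
    if covariates is None:
        covariates = sorted(c for c in table.columns if c not in RESERVED_COLUMNS)
    if not covariates:
        raise ValueError("at least one covariate required")
    work = table
    if transform == "log":
        zero = work["density"] <= 0
        if zero.any():
            logger.warning(
                "excluding %d zero-density units from log-transformed training",
                int(zero.sum()),
            )
            work = work.loc[~zero]
    if len(work) < 10:
        raise ValueError("need at least 10 training units")
    y = _transform(work["density"].to_numpy(dtype=float), transform)
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    X = work[covariates].to_numpy(dtype=float)

    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1 / 3,
        bootstrap=True,
        oob_score=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    model.fit(X, y)

    rng = np.random.default_rng((int(seed) + 0x9E3779B9) % (2**31))
    importances = pd.Series(
        _oob_importances(model, X, y, rng), index=covariates, name="inc_oob_mse"
    )
    fingerprint = hashlib.sha256(
        work[["unit_id", "density", *covariates]]
        .to_csv(index=False)
        .encode()
    ).hexdigest()[:16]
    return ForestFit(
        model=model,
        covariates=list(covariates),
        transform=transform,
        oob_var_explained=float(model.oob_score_),
        importances=importances,
        n_units=len(work),
        fingerprint=fingerprint,
    )


def predict_table(fit: ForestFit, table: pd.DataFrame) -> np.ndarray:
    """Predict density (persons/km²) for tabular covariate rows."""
    missing = [c for c in fit.covariates if c not in table.columns]
    if missing:
        raise KeyError(f"missing covariate columns: {missing}")
    X = table[fit.covariates].to_numpy(dtype=float)
    return _back_transform(fit.model.predict(X), fit.transform)


def predict_weights(fit: ForestFit, stack: CovariateStack) -> RasterGrid:
    """Per-pixel predicted density, the dasymetric weighting layer.

    Any pixel with nodata in any training covariate is nodata in the
    output.  Raises if the stack lacks a training covariate, naming it.
    """
    sub = stack.subset(fit.covariates)  # raises naming missing layers
    cube, valid = sub.as_matrix()
    order = [sub.names.index(c) for c in fit.covariates]
    X = cube[valid][:, order]
    out = np.full(stack.descriptor.shape, np.nan)
    if X.shape[0]:
        out[valid] = _back_transform(fit.model.predict(X), fit.transform)
    return stack.descriptor.copy_with(out)


def dasymetric_redistribute(
    weights: RasterGrid, admin: AdminLayer
) -> RasterGrid:
    """Allocate each unit's census count over its pixels proportionally to
    the weighting layer.

    ``pixel_pop = unit_count * weight / sum(unit weights)``; units whose
    weights sum to zero (or are all nodata) fall back to uniform allocation
    over their pixels.  Per-unit sums equal the census counts by
    construction.
    """
    if weights.shape != admin.labels.shape:
        raise ValueError("weight grid does not match admin layer")
    if admin.pixel_counts().min() == 0:
        raise ValueError("admin layer has units with zero pixels")
    lab = admin.labels.ravel()
    inside = lab >= 0
    w = np.asarray(weights.data, dtype=float).ravel().copy()
    w[~np.isfinite(w)] = 0.0
    if (w[inside] < 0).any():
        raise ValueError("weights must be non-negative")

    n = admin.n_units
    counts = admin.units["pop_count"].to_numpy(dtype=float)
    wsum = np.bincount(lab[inside], weights=w[inside], minlength=n)
    npix = admin.pixel_counts()

    fallback = wsum <= 0
    if fallback.any():
        logger.warning(
            "%d units have zero total weight; uniform fallback", int(fallback.sum())
        )
    out = np.full(lab.shape, np.nan)
    li = lab[inside]
    share = np.where(fallback[li], 1.0 / npix[li], np.divide(
        w[inside], wsum[li], out=np.zeros_like(w[inside]), where=wsum[li] > 0
    ))
    out[inside] = counts[li] * share
    return weights.copy_with(out.reshape(admin.labels.shape))
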
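"""Seeded synthetic study regions for census-disaggregation experiments.

Real inputs to this pipeline — census counts on nested administrative
levels, gridded covariates, and geolocated point events — are government or
platform data that cannot be redistributed.  This module generates a
complete stand-in region with the statistical structure the method assumes:

* spatially autocorrelated covariate fields (a binary built-up class, a
  night-lights-like intensity coupled to it, an elevation field independent
  of population, and a one-cell-wide transport corridor);
* a nested two-level administrative hierarchy built as contiguous pixel
  partitions, with integer census counts that sum exactly across levels;
* a true per-pixel population surface following a log-linear intensity in
  the covariates; and
* point events whose intensity tracks population, with controllable usage
  rate, transport-corridor bias, and neighborhood-centroid snapping — the
  documented biases of geolocated social-media data.

Everything is deterministic given ``LandscapeConfig.seed``; each generator
draws from its own named substream so stages can be rerun independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._seeds import stage_rng
from .admin import AdminLayer
from .grids import RasterGrid


class ConfigError(ValueError):
    """Invalid landscape or run configuration."""


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic study region.

    ``beta`` maps covariate names to log-linear coefficients of the
    population intensity; continuous covariates are standardized before the
    linear predictor is formed, binary ones enter as 0/1.  ``tweet_rate`` is
    the expected number of point events per person over the collection
    window; ``road_bias`` multiplies event intensity on the transport
    corridor; ``snap_fraction`` of events are relocated to the nearest of
    ``snap_centroids`` randomly placed neighborhood centroids.
    """

    seed: int
    grid_shape: tuple[int, int] = (96, 96)
    cell_size: float = 0.01
    origin: tuple[float, float] = (110.0, -5.0)  # (lon, lat) upper-left
    n_coarse_units: int = 24
    fine_per_coarse: float = 8.0
    pop_total: int = 2_000_000
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"bui_cls": 1.8, "lig": 0.7, "ele": 0.0, "roa_cls": 0.0}
    )
    noise_sd: float = 0.3
    tweet_rate: float = 0.05
    road_bias: float = 0.0
    snap_fraction: float = 0.0
    snap_centroids: int = 30

    def validate(self) -> None:
        nrows, ncols = self.grid_shape
        if nrows < 16 or ncols < 16:
            raise ConfigError("grid_shape dimensions must be >= 16")
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")
        if self.pop_total <= 0:
            raise ConfigError("pop_total must be positive")
        if self.n_coarse_units < 2:
            raise ConfigError("n_coarse_units must be >= 2")
        if self.n_coarse_units > nrows * ncols:
            raise ConfigError("n_coarse_units exceeds pixel count")
        if self.fine_per_coarse < 2:
            raise ConfigError("fine_per_coarse must be >= 2")
        if self.tweet_rate < 0:
            raise ConfigError("tweet_rate must be >= 0")
        if not 0.0 <= self.snap_fraction <= 1.0:
            raise ConfigError("snap_fraction must lie in [0, 1]")
        if self.snap_fraction > 0 and self.snap_centroids < 1:
            raise ConfigError("snap_centroids must be >= 1 when snapping")

    def empty_grid(self) -> RasterGrid:
        return RasterGrid(
            np.zeros(self.grid_shape),
            x_origin=self.origin[0],
            y_origin=self.origin[1],
            cell_size=self.cell_size,
        )


@dataclass
class SyntheticTruth:
    """A fully generated study region: the ground truth every stage is
    validated against."""

    config: LandscapeConfig
    covariates: dict[str, RasterGrid]
    true_population: RasterGrid
    admin_coarse: AdminLayer
    admin_fine: AdminLayer
    events: pd.DataFrame


# ---------------------------------------------------------------------------
# covariate fields


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _road_mask(rng: np.random.Generator, shape) -> np.ndarray:
    """One-cell-wide sinusoidal corridor crossing the grid west to east."""
    nrows, ncols = shape
    mask = np.zeros(shape, dtype=float)
    r0 = rng.uniform(0.35, 0.65) * nrows
    amp = rng.uniform(0.10, 0.20) * nrows
    phase = rng.uniform(0, 2 * np.pi)
    # dense sampling along the curve keeps the rasterized path connected
    x = np.linspace(0, ncols - 1e-6, ncols * 8)
    y = r0 + amp * np.sin(2 * np.pi * 2 * x / ncols + phase)
    rows = np.clip(y.astype(int), 0, nrows - 1)
    cols = x.astype(int)
    mask[rows, cols] = 1.0
    return mask


def generate_covariates(config: LandscapeConfig) -> dict[str, RasterGrid]:
    """Generate the aligned synthetic covariate fields.

    Returns a dict with keys ``bui_cls`` (binary built-up class), ``lig``
    (non-negative lights-like intensity coupled to the built field), ``ele``
    (elevation, independent of population), and ``roa_cls`` (binary road
    corridor).
    """
    config.validate()
    rng = stage_rng(config.seed, "covariates")
    shape = config.grid_shape
    sigma = min(shape) / 12

    base = _smooth_field(rng, shape, sigma)
    built = (base > np.quantile(base, 0.70)).astype(float)

    lights = 3.0 * gaussian_filter(built, sigma / 3, mode="reflect")
    lights = lights + 0.3 * _smooth_field(rng, shape, sigma / 2)
    lights = np.maximum(lights, 0.0)

    elevation = 500.0 + 300.0 * _smooth_field(rng, shape, sigma)

    road = _road_mask(rng, shape)

    grid = config.empty_grid()
    return {
        "bui_cls": grid.copy_with(built),
        "lig": grid.copy_with(lights),
        "ele": grid.copy_with(elevation),
        "roa_cls": grid.copy_with(road),
    }


# ---------------------------------------------------------------------------
# administrative hierarchy


def _nearest_seed_labels(
    coords: np.ndarray, seed_coords: np.ndarray
) -> np.ndarray:
    """Assign each coordinate to its nearest seed; ties -> lowest seed index."""
    d2 = ((coords[:, None, :] - seed_coords[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1).astype(np.int32)


def generate_admin_hierarchy(
    config: LandscapeConfig,
) -> tuple[AdminLayer, AdminLayer]:
    """Partition the region into coarse units and nested fine subdivisions.

    Units are grown by nearest-seed assignment on the pixel lattice, which
    yields contiguous, exactly-known pixel memberships; counts are left at
    zero until :func:`census_from_truth` fills them.
    """
    config.validate()
    rng = stage_rng(config.seed, "admin")
    nrows, ncols = config.grid_shape
    npix = nrows * ncols

    coords = np.indices(config.grid_shape).reshape(2, -1).T.astype(float)
    seed_idx = rng.choice(npix, size=config.n_coarse_units, replace=False)
    coarse_labels = _nearest_seed_labels(coords, coords[seed_idx]).reshape(
        config.grid_shape
    )

    fine_labels = np.full(config.grid_shape, -1, dtype=np.int32)
    fine_rows: list[tuple[str, str]] = []
    for u in range(config.n_coarse_units):
        unit_mask = coarse_labels == u
        unit_coords = np.argwhere(unit_mask).astype(float)
        k = max(2, int(rng.poisson(config.fine_per_coarse)))
        k = min(k, len(unit_coords))
        sub_seeds = unit_coords[
            rng.choice(len(unit_coords), size=k, replace=False)
        ]
        sub = _nearest_seed_labels(unit_coords, sub_seeds)
        parent_id = f"C{u:03d}"
        base = len(fine_rows)
        fine_labels[unit_mask] = base + sub
        fine_rows.extend((f"{parent_id}-F{j:02d}", parent_id) for j in range(k))

    grid = config.empty_grid()
    areas = grid.pixel_areas_km2().ravel()

    def _layer(labels: np.ndarray, ids: list[str], parents: list[str]) -> AdminLayer:
        unit_area = np.bincount(
            labels.ravel(), weights=areas, minlength=len(ids)
        )
        units = pd.DataFrame(
            {
                "unit_id": ids,
                "parent_id": parents,
                "pop_count": np.zeros(len(ids), dtype=np.int64),
                "area_km2": unit_area,
            }
        )
        return AdminLayer(
            labels, units, grid.x_origin, grid.y_origin, grid.cell_size
        )

    coarse_ids = [f"C{u:03d}" for u in range(config.n_coarse_units)]
    coarse = _layer(coarse_labels, coarse_ids, [""] * len(coarse_ids))
    fine = _layer(
        fine_labels, [r[0] for r in fine_rows], [r[1] for r in fine_rows]
    )
    return coarse, fine


# ---------------------------------------------------------------------------
# population surface and census counts


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``
    (largest-remainder rule), so the result sums to ``total`` exactly."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    target = weights * (total / weights.sum())
    out = np.floor(target).astype(np.int64)
    deficit = int(total - out.sum())
    if deficit:
        frac = target - out
        take = np.argsort(-frac, kind="stable")[:deficit]
        out[take] += 1
    return out


def _standardize_covariates(
    config: LandscapeConfig, covariates: Mapping[str, RasterGrid]
) -> np.ndarray:
    """Linear predictor sum(beta_k * x_k); binary layers enter raw,
    continuous layers standardized."""
    z = np.zeros(config.grid_shape)
    for name, b in config.beta.items():
        if b == 0:
            continue
        if name not in covariates:
            raise ConfigError(f"beta references unknown covariate {name!r}")
        x = np.asarray(covariates[name].data, dtype=float)
        values = np.unique(x)
        if not set(values).issubset({0.0, 1.0}):
            x = (x - x.mean()) / x.std()
        z = z + b * x
    return z


def simulate_population(
    config: LandscapeConfig, covariates: Mapping[str, RasterGrid]
) -> RasterGrid:
    """Draw the true integer population per pixel.

    Intensity is log-linear in the covariates with Gaussian log-noise;
    pixel counts are Poisson draws with mean proportional to the intensity,
    then integerized by largest remainder so the grid total equals
    ``pop_total`` exactly.
    """
    config.validate()
    rng = stage_rng(config.seed, "population")
    z = _standardize_covariates(config, covariates)
    if config.noise_sd > 0:
        z = z + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
    lam = np.exp(z)
    mean = lam * (config.pop_total / lam.sum())
    draws = rng.poisson(mean).astype(float)
    weights = draws if draws.sum() > 0 else lam
    pop = largest_remainder(weights.ravel(), config.pop_total).reshape(
        config.grid_shape
    )
    return config.empty_grid().copy_with(pop)


def census_from_truth(
    true_population: RasterGrid,
    admin_coarse: AdminLayer,
    admin_fine: AdminLayer,
) -> tuple[AdminLayer, AdminLayer]:
    """Fill unit counts with exact zonal sums of the truth grid."""
    coarse_counts = admin_coarse.zonal_sum(true_population)
    fine_counts = admin_fine.zonal_sum(true_population)
    return (
        admin_coarse.with_counts(np.rint(coarse_counts).astype(np.int64)),
        admin_fine.with_counts(np.rint(fine_counts).astype(np.int64)),
    )


# ---------------------------------------------------------------------------
# point events


def simulate_events(
    config: LandscapeConfig,
    true_population: RasterGrid,
    covariates: Mapping[str, RasterGrid],
) -> pd.DataFrame:
    """Sample geolocated point events over the region.

    The event count is Poisson with mean ``tweet_rate * pop_total``;
    locations follow population intensity inflated by ``road_bias`` on the
    corridor, jittered uniformly within the pixel; a ``snap_fraction`` share
    is then relocated to the nearest of ``snap_centroids`` random centroids,
    mimicking coordinate snapping to named neighborhoods.
    """
    config.validate()
    rng = stage_rng(config.seed, "events")
    empty = pd.DataFrame({"lon": [], "lat": []}, dtype=float)
    n = int(rng.poisson(config.tweet_rate * config.pop_total))
    if n == 0:
        return empty

    road = np.asarray(covariates["roa_cls"].data, dtype=float)
    w = np.asarray(true_population.data, dtype=float) * (
        1.0 + config.road_bias * road
    )
    if w.sum() <= 0:
        return empty
    nrows, ncols = config.grid_shape
    idx = rng.choice(nrows * ncols, size=n, p=w.ravel() / w.sum())
    rows, cols = np.divmod(idx, ncols)
    cs = config.cell_size
    lon = config.origin[0] + (cols + rng.uniform(size=n)) * cs
    lat = config.origin[1] - (rows + rng.uniform(size=n)) * cs

    m = int(round(config.snap_fraction * n))
    if m > 0:
        xmin, ymin, xmax, ymax = true_population.extent
        cx = rng.uniform(xmin, xmax, size=config.snap_centroids)
        cy = rng.uniform(ymin, ymax, size=config.snap_centroids)
        snap = rng.permutation(n)[:m]
        d2 = (lon[snap, None] - cx[None, :]) ** 2 + (
            lat[snap, None] - cy[None, :]
        ) ** 2
        nearest = d2.argmin(axis=1)
        lon[snap] = cx[nearest]
        lat[snap] = cy[nearest]

    return pd.DataFrame({"lon": lon, "lat": lat})


# ---------------------------------------------------------------------------
# orchestration


def generate_truth(config: LandscapeConfig) -> SyntheticTruth:
    """Generate the full synthetic study region from one config."""
    covariates = generate_covariates(config)
    coarse, fine = generate_admin_hierarchy(config)
    true_pop = simulate_population(config, covariates)
    coarse, fine = census_from_truth(true_pop, coarse, fine)
    events = simulate_events(config, true_pop, covariates)
    return SyntheticTruth(
        config=config,
        covariates=covariates,
        true_population=true_pop,
        admin_coarse=coarse,
        admin_fine=fine,
        events=events,
    )
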
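# Methods

## Model

Population counts `T_u` are known on coarse administrative units `u`; the
goal is a per-pixel population grid whose zonal sums reproduce every `T_u`
while the within-unit allocation follows covariates. The estimator is the
random-forest dasymetric scheme used by large-area gridded population
products:

1. For each coarse unit, compute the mean of every covariate layer over
   the unit's pixels (nodata excluded) and the observed density
   `d_u = T_u / area_u` in persons/km².
2. Fit a random forest of unpruned regression trees to `log d_u` on the
   covariate means. Defaults: 500 trees, one-third of covariates tried at
   each split, bootstrap resampling — the conventions of the regression
   forest literature. The log transform is configurable (`log` |
   `identity`); zero-density units cannot be log-transformed and are
   excluded from training with a warning.
3. Predict at every pixel from the pixel's covariate values and
   back-transform with `exp`, giving the density weighting layer. Note the
   deliberate scale mismatch: the forest is trained on unit means but
   applied to pixel values. Tree predictions are bounded by the training
   response range, so pixel-level extremes saturate; this is immaterial
   for redistribution, which uses only within-unit *relative* weights.
4. Redistribute `pop(p) = T_u(p) · w(p) / Σ_{q∈u} w(q)`. Units whose
   weights sum to zero (or are entirely nodata) fall back to uniform
   allocation over their pixels, logged. Conservation of every unit total
   is then an algebraic identity, and tests require it to 1e-6 relative.

### OOB diagnostics

OOB variance explained is `1 − MSE_oob / Var(y)` on the forest's own
out-of-bag predictions. Permutation importance is computed by this package
on the per-tree bootstrap structure: for each tree, take its out-of-bag
units, record the tree's OOB MSE, permute one covariate among those rows,
re-predict, and record the MSE increase; importances are the per-tree
increases averaged over trees. Values near zero (slightly negative is
possible) mean the covariate carries no signal; an all-constant covariate
has exactly zero importance because permuting it changes nothing.

### Validation design

Models are trained at the coarse level only; accuracy is measured by
aggregating the predicted pixel map to the *finer* nested census level and
comparing with the counts held in reserve: RMSE, %RMSE = 100·RMSE / mean
observed count over exactly the compared units, MAE. Two arms — identical
except that one stack includes the event-density layer — are differenced
as (without − with). Display rounding is 2 decimals for all three
statistics; computation is full precision. ASR = √(total area / number of
units) summarizes mean unit size in km.

## Event gridding

Events are binned by flooring each coordinate to the cell size: cell
origins at `floor(coord / c) · c`, cells half-open `[origin, origin + c)`.
Floor toward −∞ (not truncation toward zero) keeps the partition consistent
across the equator and prime meridian. Aggregation onto the modelling grid
assigns each source cell to the target cell containing its center and
sums, conserving total count; refinement to a finer grid uses the
nearest-cell value. The event covariate is the raw count per modelling
cell; no kernel smoothing.

## Covariate stack

`*_cls` layers are binary class membership; `*_dst` layers are Euclidean
distances from each pixel center to the nearest class pixel center,
computed with an exact Euclidean distance transform in cell units scaled
by the cell size. Distances are therefore planar degrees, not geodesic
metres — the convention of the GIS tooling this method descends from, kept
here because it makes the brute-force test oracle exact. Known limitation:
at high latitudes a degree of longitude shrinks, so planar degree
distances increasingly overweight east–west separation. Nodata pixels are
excluded from both the class set and the distance domain, so masked-out
water cannot anchor a distance.

## Synthetic study region

The generator emulates the data regime the method assumes, at desk scale:

- **Covariates:** a smoothed Gaussian field thresholded at its 70th
  percentile gives the binary built-up class (~30% built); the lights
  layer is a blurred copy of the built field plus independent smooth noise
  (correlation with built ≈ 0.7–0.9), clipped non-negative; elevation is
  an independent smooth field (500 ± 300 m); the road is a one-cell-wide
  sinusoidal corridor.
- **Admin hierarchy:** coarse units by nearest-seed assignment on the
  pixel lattice (contiguous, convex-ish, exactly known pixel memberships);
  each coarse unit subdivided the same way into ≥2 fine units (Poisson
  mean `fine_per_coarse`). Polygon export derives boundaries from pixel
  membership, so GeoJSON round-trips rasterize back to identical labels.
- **Population:** `λ(p) = exp(Σ β_k x_k(p) + ε)`, `ε ~ N(0, noise_sd²)`;
  pixel counts are Poisson draws with mean proportional to λ, integerized
  by largest-remainder apportionment so the grid totals `pop_total`
  exactly. Census counts are exact zonal sums, so cross-level consistency
  is exact by construction.
- **Events:** count Poisson with mean `tweet_rate · pop_total`; locations
  sampled ∝ `population · (1 + road_bias · road)` with uniform in-cell
  jitter; a `snap_fraction` share relocated to the nearest of
  `snap_centroids` random centroids — the transport-corridor and
  neighborhood-snapping biases documented for geolocated social-media
  data.

Defaults: 96×96 grid at 0.01°, 24 coarse units, ~8 fine per coarse
(coarse:fine ratio ≈ 1:8, echoing national level-3 : level-4 ratios),
2,000,000 people, β = {built 1.8, lights 0.7}, `noise_sd` 0.3,
`tweet_rate` 0.05 events/person, `road_bias` 0 and `snap_fraction` 0 (the
bias knobs are exercised in tests, off by default). One run seed fans out
to per-stage substreams by hashing stage names, so any stage reruns
identically in isolation; all artifacts are byte-reproducible from config
plus seed.

What the generator does *not* emulate: real settlement morphology and
coastlines (the region is a full rectangle; nodata handling is tested with
synthetic masks), diurnal or demographic structure in events, spatially
varying usage rates, and covariate measurement error. Passing tests show
the pipeline recovers a population surface generated *from its own
covariate family* and that an informative activity layer is detected and
exploited; they do not certify accuracy on real landscapes.

## Numerical choices

- Pixel areas use a per-row spherical approximation,
  `(c·111.3195 km)²·cos(lat)`; admin areas are sums of pixel areas.
- Each pixel belongs to exactly one unit; GeoJSON rasterization assigns
  pixel centers to polygons scanned in `unit_id` order, first match wins,
  so boundary ties break toward the lowest id.
- Forest determinism: the scikit-learn forest is seeded; the permutation
  RNG derives from the same seed. Refit with the same table and seed gives
  identical importances.
- The paired-experiment seed fan-out gives each arm its own fit seed;
  with `tweet_rate = 0` the arms differ only by an all-zero covariate,
  whose importance is exactly zero and whose effect on paired RMSE stays
  within the seed-to-seed spread.
- Desk-scale problem sizes throughout (96×96 default grid, 10-seed
  replication sets, 5-seed recovery and degeneracy sets) keep every full
  experiment under ~2 s and the whole suite a few minutes while leaving
  enough fine units (~190) for stable validation statistics. The
  low-noise recovery check (`noise_sd` 0.1, %RMSE ≤ 30%) is asserted on
  the mean over five fixed seeds, since single-seed values fluctuate by
  several points.

## Known limitations

- Planar-degree distances (above).
- No covariate selection or hyperparameter search; the full supplied
  stack enters the forest.
- Prediction happens on the covariate grid; no sub-pixel areal weighting.
- The event covariate enters as raw counts; usage-rate heterogeneity
  across regions would confound it and is not modelled.
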
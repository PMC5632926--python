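# Methods

## Model

The package implements top-down dasymetric population mapping.  The unit
of inference is the admin zone; the response is the natural log of
population density, `ln(N_z / A_z)`, with `A_z` the area of the zone's
*non-excluded* cells.  Using the unmasked area (rather than the full
polygon area) keeps the training response consistent with the support on
which predictions are later renormalized: people are defined to live only
on unmasked cells.  The density unit (per km², per hectare, …) shifts the
log response by a constant that cancels in the within-zone renormalization,
so no unit convention is imposed.

The regressor is a random forest (scikit-learn `RandomForestRegressor`)
with 500 trees by default, `mtry = ⌊p/3⌋` features per split (the
regression-forest convention), unlimited depth, bootstrap resampling, and
a fixed seed; all are overridable.  Predictions are back-transformed with
a plain `exp` — no smearing correction, because the surface is immediately
renormalized within zones, cancelling any multiplicative factor.

Zones with zero population or zero unmasked area are dropped from training
(and counted in the fit summary) rather than given an `ln(0+ε)` epsilon,
which would leak an arbitrary constant into the response.  Fitting refuses
to proceed with fewer than 10 usable zones.

## Exclusion masking

The exclusion mask is the union of protected areas and Euclidean buffers
(default 200 length units) around coastline and main-road cells.  Buffers
use exact cell-centre-to-cell-centre distances (`scipy.ndimage`
`distance_transform_edt`); a cell is buffered when its centre lies within
the buffer distance of a feature cell centre.  Masked cells receive weight
0 and therefore zero population.

## Covariates

Each census-year stack contains: interpolated built-up percentage; per
non-built land-cover class a binary class layer and an exact-Euclidean
distance-to layer; distance to roads; distance to rivers; elevation;
slope — `1 + 2·n_classes + 4` layers (23 with the default nine classes).
Built-up percentage is interpolated linearly between the two epochs
bracketing the target year on its native grid and clamped to [0, 100]
(it is a percentage by definition); extrapolation outside the epoch span
is refused.  All layers are nearest-neighbour resampled onto one declared
reference grid; resampling onto a grid's own geometry is the identity.
Zonal covariates are means for continuous layers and majority codes for
binary/categorical ones, ties breaking toward the smaller code for
determinism.  A distance-to layer for a class absent from the domain is a
constant equal to the grid diagonal, with a warning: the forest needs a
fixed feature schema between training and prediction years, so the layer
must exist, and the diagonal is an honest "farther than anything on the
map" value.  Whether built-up should additionally enter as a
distance-to-settlement layer is unsettled; only the percentage layer is
included by default, with `include_dist_builtup=True` available.

## Importance

Covariate importance is the out-of-bag permutation %IncMSE:
`100·(MSE_oob(permuted) − MSE_oob)/MSE_oob`, averaged over seeded
shuffles (default 5).  In-bag index sets are reconstructed by replaying
each tree's seeded bootstrap draw; a unit test verifies the replayed OOB
predictions match the forest's own `oob_prediction_` exactly.  The
percent normalization (rather than a raw MSE difference) makes values
comparable across models.  Ranks break ties by covariate name.

## Scheme comparison

M1 fits once at the finest admin level of a designated training year and
transfers the model; M2 fits per year at that year's own level.  Both
redistribute *coarse*-level counts, which are always derived by
aggregating the evaluation-level census upward through the zone hierarchy
— never taken as independent inputs — so predicted and observed coarse
totals coincide by construction and evaluation-level residuals cancel
within each coarse zone (the conservation-transfer property).  RMSE and
MAE are computed on raw counts, matching how census-based validation is
usually reported; per-capita variants can be derived from the returned
residual tables.  Per-year M2 forests draw seeds from a shared stream
(`seed + year index`) so runs are reproducible without coupling years.
Final surfaces default to the M1 scheme (one consistent model across the
series); `PipelineConfig.final_scheme` switches this.

## Synthetic scenes

The generator emulates the study conditions end to end, with known ground
truth:

* **Admin hierarchy** — seeded Voronoi subdivision of the grid, coarsest
  level first, each level partitioning its parent zones around seed cells
  drawn inside them; nesting is guaranteed by construction.  Defaults: 8
  coarse ("district"), 40 fine ("sub-location"), 200 finest ("enumeration
  area") zones, mirroring the relative unit counts of a small coastal
  study area.
* **Settlement** — a few urban cores (Gaussian bumps) whose amplitude and
  extent grow ~3.5 %/yr across the epochs 1975/1990/2000/2014, plus
  smooth speckle, clamped to [0, 100] %.
* **Geography** — smoothed random fields quantized into nine land-cover
  classes; a smooth elevation field with derived slope; sinusoidal road
  and river polylines; an eastern-edge coastline; three rectangular
  protected areas.
* **Truth density** — per census year,
  `exp( ln(rural) + Σ_j c_{jt}·z_j + σ·ε )` on habitable cells, where
  `z_j` are standardized `log1p` covariate layers, `c_{jt}` are the
  configured coefficients (allowed to differ per year: relationship
  drift), `σ` is the log-scale noise sd (default 0.3, a moderate
  unexplained-density level), and `rural` is a baseline rural density
  (default 2 people/cell) so unsettled areas are populated.  Truth is zero
  on the full exclusion mask (protected areas *and* road/coast buffers) by
  default, keeping the generated world consistent with the model's
  exclusion assumption; `exclude_buffers_in_truth=False` relaxes this.
* **Growth** — each coarse zone's total follows compound growth
  `P_z(t) = P_z(t₀)·(1+r_z)^(t−t₀)` with `r = 0.033/yr` by default
  (the order of the published coastal growth rates, giving a ×2.65 rise
  over 30 years); the domain total at the first census year is scaled to
  `domain_population` (default 10⁶).  Census tables at every level are
  exact zonal sums of the truth, stored real-valued so conservation
  checks are exact; a largest-remainder integerization is provided for
  realism.

Two named configurations freeze the conditions used by the stochastic
checks: `recovery_scene_config` (drift-free, settlement-dominated density)
and `drifted_scene_config` (four years, drift concentrated in the first
year: settlement down-weighted, road and cultivated-land effects flipped —
a strong but localized relationship change).

**What the generator does not emulate:** realistic urban-growth
morphology, geographic (lat/lon) coordinates and geodesic distances,
boundary changes between censuses, census undercount or rounding error,
and spatially autocorrelated noise in density beyond what the smooth
covariates induce.  Passing tests therefore demonstrate the machinery's
correctness and the schemes' qualitative behaviour under controlled drift,
not the accuracy attainable on real national data.

## Numerical choices

* Conservation is exact up to floating-point summation (~1e-15 relative);
  tests use 1e-9.
* Zero-weight zones with people fall back to uniform allocation over the
  zone's unmasked cells (all cells if fully masked), with a warning.
* Cell-to-zone assignment is by cell centre; GeoJSON rasterization assigns
  boundary centres to the smaller zone id (first-winner in ascending id
  order).
* Rasters serialize as ESRI ASCII grids: a ubiquitous plain-text format
  carrying exactly the grid metadata the package uses (shape, origin,
  cell size, nodata); floats are written with 17 significant digits so
  round trips are lossless at float64.
* Scene RNG streams are spawned per stage from one `SeedSequence`, so
  changing one stage's draws does not cascade into others.

## Problem sizes

Tests and the acceptance script run on scaled-down scenes: 200×200 cells
for the conservation check, 100×100 (150 trees) for the 20-seed recovery
experiments, 80×80 (100 trees) for the 20-seed drift experiments.  These
sizes keep the full suite at desk scale while leaving dozens of training
units per model and thousands of cells per zone — comfortably in the
regime where the method's qualitative behaviour is stable.

## Known limitations

* The forest cannot extrapolate beyond the training response range, so
  densities in units far outside the training distribution saturate.
* M2's evaluation shares data with its training (each year's model trains
  at the level that is also aggregated for validation), as in the standard
  study design this mirrors; the comparison is therefore generous to M2.
* Absent-class distance layers (constant diagonal) carry no information
  and slightly dilute `mtry`; they exist to stabilize the schema.
* Only linear temporal interpolation of settlement is provided; spline or
  logistic growth interpolation is out of scope.
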
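"""Per-year covariate stacks for density modelling.

The stack for a census year combines a temporally interpolated built-up
percentage layer with time-invariant geography: per land-cover class a binary
"class" layer and an exact-Euclidean "distance-to" layer, distance to main
roads, distance to permanent rivers, elevation and slope.  All layers are
nearest-neighbour co-registered onto one reference grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterGrid, check_coregistered, resample_nearest
from .zones import AdminZoneSet

log = logging.getLogger(__name__)

BUILTUP = "builtup_pct"
DIST_ROADS = "dist_roads"
DIST_RIVERS = "dist_rivers"
ELEVATION = "elevation"
SLOPE = "slope"

#: Aggregated non-built land-cover classes (code -> name).
DEFAULT_LC_CLASSES: dict[int, str] = {
    1: "cultivated",
    2: "woody_trees",
    3: "shrubs",
    4: "herbaceous",
    5: "sparse_veg",
    6: "aquatic_veg",
    7: "bare",
    8: "water",
    9: "lc_nodata",
}


@dataclass
class CovariateStack:
    """Named, co-registered covariate layers for one target year."""

    year: int
    layers: dict[str, RasterGrid]
    categorical_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        if grids:
            check_coregistered(*grids)
        unknown = self.categorical_names - set(self.layers)
        if unknown:
            raise ValueError(f"categorical names not in layers: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def as_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(n_cells, n_layers) feature matrix in row-major cell order."""
        names = names or self.names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack for year {self.year} is missing layers: {missing}")
        return np.column_stack([self.layers[n].values.ravel() for n in names])


@dataclass
class InterpolationSpec:
    """Inputs for linear interpolation of built-up percentage to year ``t``.

    ``b_t1``/``b_t2`` are the built-up layers at the bracketing epochs
    ``t1 <= t <= t2``; values are percentages in [0, 100] or nodata.
    """

    t: int
    t1: int
    t2: int
    b_t1: RasterGrid
    b_t2: RasterGrid

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError(f"need t1 < t2, got {self.t1} >= {self.t2}")
        if not self.t1 <= self.t <= self.t2:
            raise ValueError(
                f"target year {self.t} outside [{self.t1}, {self.t2}]; "
                "extrapolation is refused"
            )
        check_coregistered(self.b_t1, self.b_t2)


def interpolate_builtup(spec: InterpolationSpec) -> RasterGrid:
    """Linearly interpolate built-up percentage to the target year.

    Per cell ``B_t = B_t1 + (t - t1)/(t2 - t1) * (B_t2 - B_t1)``; nodata in
    either input propagates; the output is clamped to [0, 100] (the quantity
    is a percentage by definition).
    """
    frac = (spec.t - spec.t1) / (spec.t2 - spec.t1)
    v1 = np.asarray(spec.b_t1.values, dtype=float)
    v2 = np.asarray(spec.b_t2.values, dtype=float)
    out = v1 + frac * (v2 - v1)
    np.clip(out, 0.0, 100.0, out=out)
    invalid = ~(spec.b_t1.valid_mask() & spec.b_t2.valid_mask())
    out[invalid] = spec.b_t1.nodata
    return spec.b_t1.with_values(out)


def select_bracketing_epochs(target_year: int, epochs: list[int]) -> tuple[int, int]:
    """Nearest epoch <= target and nearest epoch >= target.

    If the target coincides with an epoch, returns ``(target, next epoch)``
    (interpolation then reduces to the identity); for the last epoch the
    preceding one is used so the pair still brackets the target.
    """
    epochs = sorted(epochs)
    if len(epochs) < 2:
        raise ValueError("need at least two epochs")
    if not epochs[0] <= target_year <= epochs[-1]:
        raise ValueError(
            f"target year {target_year} outside epoch span [{epochs[0]}, {epochs[-1]}]"
        )
    below = max(e for e in epochs if e <= target_year)
    if below == epochs[-1]:
        return epochs[-2], epochs[-1]
    above = min(e for e in epochs if e > below)
    return below, above


def distance_to_class(categorical: RasterGrid, class_codes: set[int]) -> RasterGrid:
    """Exact planar Euclidean distance to the nearest cell of given class.

    Member cells get 0.  If no cell belongs to the class, the layer is a
    constant equal to the grid diagonal (a documented "absent" sentinel that
    keeps the feature schema fixed across years) and a warning is emitted.
    """
    member = np.isin(categorical.values, list(class_codes))
    n_rows, n_cols = categorical.shape
    if not member.any():
        diag = float(np.hypot(n_rows, n_cols) * categorical.cell_size)
        warnings.warn(
            f"classes {sorted(class_codes)} absent from domain; "
            f"distance layer set to grid diagonal {diag:.1f}",
            stacklevel=2,
        )
        log.warning("distance_to_class: classes %s absent", sorted(class_codes))
        return categorical.with_values(np.full(categorical.shape, diag))
    dist = ndimage.distance_transform_edt(~member, sampling=categorical.cell_size)
    return categorical.with_values(dist)


def build_stack(
    *,
    year: int,
    builtup_by_epoch: dict[int, RasterGrid],
    landcover: RasterGrid,
    elevation: RasterGrid,
    slope: RasterGrid,
    road_mask: RasterGrid,
    river_mask: RasterGrid,
    reference: RasterGrid | None = None,
    lc_classes: dict[int, str] | None = None,
    include_dist_builtup: bool = False,
) -> CovariateStack:
    """Assemble the co-registered covariate stack for one census year.

    Built-up is interpolated between the epochs bracketing ``year`` on its
    native grid, then (like every other layer) nearest-neighbour resampled to
    the reference grid.  Land cover contributes a binary class layer and a
    distance-to layer per non-built class, so the layer count is
    ``1 + 2 * n_classes + 4`` (+1 if ``include_dist_builtup``).

    For multiple land-cover eras pass the era's map as ``landcover``
    (callers hold the year -> source mapping).
    """
    required = {
        "landcover": landcover,
        "elevation": elevation,
        "slope": slope,
        "road_mask": road_mask,
        "river_mask": river_mask,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ValueError(f"missing required layers: {missing}")
    if not builtup_by_epoch:
        raise ValueError("missing required layers: ['builtup_by_epoch']")

    reference = reference or landcover
    t1, t2 = select_bracketing_epochs(year, list(builtup_by_epoch))
    bu = interpolate_builtup(
        InterpolationSpec(year, t1, t2, builtup_by_epoch[t1], builtup_by_epoch[t2])
    )

    lc_classes = lc_classes or DEFAULT_LC_CLASSES
    lc = resample_nearest(landcover, reference)
    layers: dict[str, RasterGrid] = {BUILTUP: resample_nearest(bu, reference)}
    categorical: set[str] = set()
    for code, name in sorted(lc_classes.items()):
        cls = lc.with_values((lc.values == code).astype(np.int16))
        layers[f"class_{name}"] = cls
        categorical.add(f"class_{name}")
        layers[f"dist_{name}"] = distance_to_class(lc, {code})
    layers[DIST_ROADS] = distance_to_class(resample_nearest(road_mask, reference), {1})
    layers[DIST_RIVERS] = distance_to_class(resample_nearest(river_mask, reference), {1})
    layers[ELEVATION] = resample_nearest(elevation, reference)
    layers[SLOPE] = resample_nearest(slope, reference)
    if include_dist_builtup:
        settled = layers[BUILTUP].with_values(
            (layers[BUILTUP].values > 0).astype(np.int16)
        )
        layers["dist_builtup"] = distance_to_class(settled, {1})
    return CovariateStack(year=year, layers=layers, categorical_names=categorical)


def zonal_aggregate(stack: CovariateStack, zones: AdminZoneSet) -> pd.DataFrame:
    """One row per zone: zonal mean per continuous layer, majority per
    categorical/binary layer (ties break toward the smaller code).

    Zones with zero valid cells get NaN for the layer and are flagged in the
    boolean ``empty`` column rather than raising.
    """
    check_coregistered(zones.labels, *stack.layers.values())
    labels = zones.labels.values.ravel()
    ids = zones.zone_ids
    out = pd.DataFrame(index=pd.Index(ids, name="zone_id"))
    n_bins = int(labels.max()) + 1
    any_empty = np.zeros(ids.size, dtype=bool)
    for name, grid in stack.layers.items():
        valid = grid.valid_mask().ravel()
        vals = np.asarray(grid.values, dtype=float).ravel()
        if name in stack.categorical_names:
            col = np.full(ids.size, np.nan)
            for i, zid in enumerate(ids):
                sel = (labels == zid) & valid
                if not sel.any():
                    any_empty[i] = True
                    continue
                codes, counts = np.unique(vals[sel], return_counts=True)
                col[i] = codes[np.argmax(counts)]  # unique() sorts: tie -> smallest
            out[name] = col
        else:
            sums = np.bincount(labels, weights=np.where(valid, vals, 0.0), minlength=n_bins)
            cnts = np.bincount(labels, weights=valid.astype(float), minlength=n_bins)
            with np.errstate(invalid="ignore"):
                means = np.where(cnts[ids] > 0, sums[ids] / cnts[ids], np.nan)
            any_empty |= cnts[ids] == 0
            out[name] = means
    out["empty"] = any_empty
    if any_empty.any():
        log.warning("zonal_aggregate: %d zones with no valid cells", any_empty.sum())
    return out.reset_index()
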
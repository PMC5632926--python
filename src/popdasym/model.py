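"""Random-forest dasymetric density model.

The core estimator of the package: a regression forest is fitted to the
log population density of admin units (response ``ln(count / unmasked
area)``), with zonally aggregated covariates as features.  The fitted
forest predicts a pixel-level relative-density surface which, after
exclusion masking, serves as the weighting layer of a standard dasymetric
redistribution: census counts are split among a zone's cells in proportion
to their weights, so zonal sums reproduce the counts exactly.

Organisation follows the Model/Results convention: build a
:class:`DasymetricModel` from data, call :meth:`~DasymetricModel.fit`, and
work with the returned :class:`DasymetricResults` (weight prediction,
permutation importance, ``summary()``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils import check_random_state

from .raster import RasterGrid, check_coregistered
from .zones import AdminZoneSet

log = logging.getLogger(__name__)

DEFAULT_BUFFER = 200.0
DEFAULT_N_TREES = 500
MIN_USABLE_ZONES = 10


def build_exclusion_mask(
    protected: RasterGrid,
    roads: RasterGrid,
    coastline: RasterGrid,
    buffer_distance: float = DEFAULT_BUFFER,
) -> RasterGrid:
    """Cells where no people are allowed to live.

    Union of protected areas and Euclidean buffers of ``buffer_distance``
    (default 200 length units) around road and coastline cells; a cell is
    buffered when its centre lies within the distance of a feature cell
    centre.
    """
    check_coregistered(protected, roads, coastline)
    out = protected.values.astype(bool).copy()
    for feat in (roads, coastline):
        member = feat.values.astype(bool)
        if member.any():
            dist = ndimage.distance_transform_edt(~member, sampling=feat.cell_size)
            out |= dist <= buffer_distance + 1e-9
    return protected.with_values(out.astype(np.int16))


@dataclass
class WeightSurface:
    """Nonnegative dasymetric weights, zero on excluded cells."""

    weights: RasterGrid
    mask: RasterGrid

    def __post_init__(self) -> None:
        check_coregistered(self.weights, self.mask)
        w = self.weights.values
        if not np.all(np.isfinite(w)) or (w < 0).any():
            raise ValueError("weights must be finite and nonnegative")
        if w[self.mask.values.astype(bool)].any():
            raise ValueError("weights must be zero on masked cells")


@dataclass
class PopulationSurface:
    """People-per-cell grid whose zonal sums equal the source census."""

    people_per_cell: RasterGrid
    provenance: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(self.people_per_cell.values.sum())


def unmasked_zone_area(zones: AdminZoneSet, mask: RasterGrid) -> pd.Series:
    """Area (in squared length units) of non-excluded cells per zone."""
    check_coregistered(zones.labels, mask)
    free = (~mask.values.astype(bool)).ravel().astype(float)
    labels = zones.labels.values.ravel()
    counts = np.bincount(labels, weights=free)
    ids = zones.zone_ids
    return pd.Series(
        counts[ids] * zones.labels.cell_area,
        index=pd.Index(ids, name="zone_id"),
        name="unmasked_area",
    )


class DasymetricModel:
    """Log-density regression forest over admin units.

    Parameters
    ----------
    zonal_table : DataFrame
        One row per zone: ``zone_id`` plus one column per covariate
        (output of :func:`popdasym.covariates.zonal_aggregate`).
    census : DataFrame
        Columns ``zone_id`` and ``population`` for the training year/level.
    zones : AdminZoneSet
        Training-level zones, used to measure unmasked areas.
    exclusion : RasterGrid
        Binary exclusion mask; the density denominator is the area of
        non-excluded cells, matching the support on which predictions are
        later renormalized.
    feature_names : list of str, optional
        Covariates to use; defaults to every non-bookkeeping column of
        ``zonal_table``.
    n_trees, mtry, max_depth, seed :
        Forest hyperparameters; ``mtry`` defaults to ``n_features // 3``
        (regression-forest convention), depth unlimited.
    """

    def __init__(
        self,
        zonal_table: pd.DataFrame,
        census: pd.DataFrame,
        zones: AdminZoneSet,
        exclusion: RasterGrid,
        feature_names: list[str] | None = None,
        n_trees: int = DEFAULT_N_TREES,
        mtry: int | None = None,
        max_depth: int | None = None,
        seed: int = 0,
        training_year: int | None = None,
        training_level: int | None = None,
    ) -> None:
        drop = {"zone_id", "empty"}
        self.feature_names = feature_names or [
            c for c in zonal_table.columns if c not in drop
        ]
        if not self.feature_names:
            raise ValueError("feature schema is empty")
        self.n_trees = n_trees
        self.mtry = mtry
        self.max_depth = max_depth
        self.seed = seed
        self.training_year = training_year
        self.training_level = training_level

        areas = unmasked_zone_area(zones, exclusion)
        df = zonal_table.merge(census[["zone_id", "population"]], on="zone_id")
        missing = set(census["zone_id"]) - set(zonal_table["zone_id"])
        if missing:
            raise ValueError(f"census zones missing a covariate row: {sorted(missing)[:5]}")
        df["unmasked_area"] = df["zone_id"].map(areas)

        usable = (df["population"] > 0) & (df["unmasked_area"] > 0)
        if "empty" in zonal_table.columns:
            usable &= ~df["zone_id"].map(
                zonal_table.set_index("zone_id")["empty"]
            ).astype(bool)
        n_dropped = int((~usable).sum())
        if n_dropped:
            log.info(
                "dropping %d degenerate zones (zero population or fully masked)",
                n_dropped,
            )
        self.train = df[usable].reset_index(drop=True)
        self.n_dropped = n_dropped
        if len(self.train) == 0:
            raise ValueError("all zones are degenerate (zero population or masked)")
        if len(self.train) < MIN_USABLE_ZONES:
            raise ValueError(
                f"only {len(self.train)} usable zones; need >= {MIN_USABLE_ZONES}"
            )
        self.response = np.log(
            self.train["population"].to_numpy() / self.train["unmasked_area"].to_numpy()
        )

    @classmethod
    def from_scene(
        cls,
        scene,
        year: int,
        level: int,
        stack=None,
        **kwargs,
    ) -> "DasymetricModel":
        """Convenience constructor from a synthetic scene."""
        from .covariates import zonal_aggregate

        stack = stack or scene.stack_for_year(year)
        zones = scene.zones_by_level[level]
        return cls(
            zonal_aggregate(stack, zones),
            scene.census_by_level_year[(level, year)],
            zones,
            scene.exclusion_mask,
            training_year=year,
            training_level=level,
            **kwargs,
        )

    def fit(self) -> "DasymetricResults":
        X = self.train[self.feature_names].to_numpy(float)
        mtry = self.mtry if self.mtry is not None else max(1, len(self.feature_names) // 3)
        forest = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=mtry,
            max_depth=self.max_depth,
            oob_score=True,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        forest.fit(X, self.response)
        return DasymetricResults(self, forest)


class DasymetricResults:
    """Fitted dasymetric density model: diagnostics, weights, importance."""

    def __init__(self, model: DasymetricModel, forest: RandomForestRegressor) -> None:
        self.model = model
        self.forest = forest
        self.feature_names = model.feature_names
        self.oob_prediction = forest.oob_prediction_
        resid = model.response - self.oob_prediction
        self.oob_mse = float(np.mean(resid**2))
        self.oob_r2 = float(forest.oob_score_)
        self.training_meta = {
            "year": model.training_year,
            "level": model.training_level,
            "n_units": len(model.train),
            "n_dropped": model.n_dropped,
            "seed": model.seed,
            "n_trees": model.n_trees,
            "mtry": forest.max_features,
            "max_depth": model.max_depth,
            "features": list(model.feature_names),
        }

    # ------------------------------------------------------------------ #
    def predict_weight_surface(self, stack, mask: RasterGrid) -> WeightSurface:
        """Pixel-level dasymetric weights from a covariate stack.

        Per unmasked cell ``exp(forest log-density prediction)``; masked
        cells get 0.  Only within-zone ratios matter downstream, so the
        plain exponential back-transform needs no bias correction.
        """
        return predict_weight_surface(self.forest, stack, mask, self.feature_names)

    def importance(
        self, n_permutations: int = 5, seed: int = 0
    ) -> pd.DataFrame:
        """Out-of-bag permutation importance (%IncMSE) per covariate.

        ``100 * (MSE_oob(permuted) - MSE_oob(original)) / MSE_oob(original)``,
        averaged over seeded shuffles; ranks break ties by covariate name.
        """
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        X = self.model.train[self.feature_names].to_numpy(float)
        y = self.model.response
        n = len(y)
        inbag = _inbag_matrix(self.forest, n)
        base_pred = _oob_prediction(self.forest, X, inbag)
        base_mse = float(np.mean((y - base_pred) ** 2))
        rng = np.random.default_rng(seed)
        rows = []
        for j, name in enumerate(self.feature_names):
            incs = []
            for _ in range(n_permutations):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(n), j]
                mse = float(np.mean((y - _oob_prediction(self.forest, Xp, inbag)) ** 2))
                incs.append(100.0 * (mse - base_mse) / base_mse)
            rows.append({"covariate": name, "pct_increase_mse": float(np.mean(incs))})
        out = pd.DataFrame(rows).sort_values(
            ["pct_increase_mse", "covariate"], ascending=[False, True]
        )
        out["rank"] = np.arange(1, len(out) + 1)
        return out.sort_values("covariate").reset_index(drop=True)

    def summary(self) -> str:
        meta = self.training_meta
        lines = [
            "Random-forest dasymetric density model",
            "=" * 54,
            f"response           ln(population / unmasked area)",
            f"training year      {meta['year']}",
            f"admin level        {meta['level']}",
            f"n units used       {meta['n_units']}",
            f"n units dropped    {meta['n_dropped']}",
            f"n covariates       {len(self.feature_names)}",
            f"trees / mtry       {meta['n_trees']} / {meta['mtry']}",
            f"OOB MSE            {self.oob_mse:.4f}",
            f"OOB R^2            {self.oob_r2:.4f}",
            "=" * 54,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
# functional layer


def _inbag_matrix(forest: RandomForestRegressor, n_samples: int) -> np.ndarray:
    """(n_trees, n_samples) bootstrap-use counts, replaying each tree's
    seeded draw (same scheme the forest used at fit time)."""
    counts = np.zeros((len(forest.estimators_), n_samples), dtype=np.int32)
    for i, est in enumerate(forest.estimators_):
        rs = check_random_state(est.random_state)
        idx = rs.randint(0, n_samples, n_samples)
        np.add.at(counts[i], idx, 1)
    return counts


def _oob_prediction(
    forest: RandomForestRegressor, X: np.ndarray, inbag: np.ndarray
) -> np.ndarray:
    """Mean prediction per sample over the trees that did not see it."""
    n = X.shape[0]
    total = np.zeros(n)
    n_oob = np.zeros(n)
    for i, est in enumerate(forest.estimators_):
        oob = inbag[i] == 0
        if not oob.any():
            continue
        total[oob] += est.predict(X[oob])
        n_oob[oob] += 1
    if (n_oob == 0).any():
        log.warning("%d samples never out-of-bag; using forest mean", (n_oob == 0).sum())
        total[n_oob == 0] = forest.predict(X[n_oob == 0])
        n_oob[n_oob == 0] = 1
    return total / n_oob


def predict_weight_surface(
    predictor, stack, mask: RasterGrid, feature_names: list[str]
) -> WeightSurface:
    """Weights from any fitted log-density regressor (forest or constant)."""
    X = stack.as_matrix(feature_names)
    n_expected = getattr(predictor, "n_features_in_", X.shape[1])
    if n_expected != X.shape[1]:
        raise ValueError(
            f"feature schema mismatch: model expects {n_expected}, stack gives "
            f"{X.shape[1]} ({feature_names})"
        )
    ref = next(iter(stack.layers.values()))
    check_coregistered(ref, mask)
    masked = mask.values.astype(bool)
    weights = np.zeros(ref.shape)
    free = ~masked
    if free.any():
        pred = predictor.predict(X[free.ravel()])
        weights[free] = np.exp(pred)
    if not np.all(np.isfinite(weights)):
        raise FloatingPointError("non-finite weights predicted")
    return WeightSurface(ref.with_values(weights), mask)


def areal_weight_surface(reference: RasterGrid, mask: RasterGrid) -> WeightSurface:
    """Uniform weights over unmasked cells — the areal-weighting baseline."""
    free = ~mask.values.astype(bool)
    return WeightSurface(reference.with_values(free.astype(float)), mask)


def dasymetric_redistribute(
    weights: WeightSurface,
    zones: AdminZoneSet,
    census: pd.DataFrame,
    provenance: dict | None = None,
) -> PopulationSurface:
    """Split census counts among each zone's cells proportionally to weights.

    Zones whose weights sum to 0 but hold people fall back to uniform
    allocation over the zone's unmasked cells (or all its cells when fully
    masked), with a logged warning.  Per-zone output sums equal the census
    counts to floating precision.
    """
    check_coregistered(weights.weights, zones.labels)
    labels = zones.labels.values
    w = weights.weights.values
    masked = weights.mask.values.astype(bool)
    zone_ids = set(int(z) for z in zones.zone_ids)
    people = np.zeros(w.shape)
    n_fallback = 0
    for _, rec in census.iterrows():
        zid, count = int(rec["zone_id"]), float(rec["population"])
        if zid not in zone_ids:
            raise ValueError(f"census zone {zid} missing from zone set")
        sel = labels == zid
        wsum = w[sel].sum()
        if wsum > 0:
            people[sel] = count * w[sel] / wsum
        elif count > 0:
            support = sel & ~masked
            if not support.any():
                support = sel
            people[support] = count / support.sum()
            n_fallback += 1
    if n_fallback:
        log.warning(
            "dasymetric_redistribute: %d zero-weight zones fell back to uniform",
            n_fallback,
        )
    prov = {"n_fallback_zones": n_fallback, **(provenance or {})}
    return PopulationSurface(weights.weights.with_values(people), prov)
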
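"""Seeded synthetic landscapes with known population ground truth.

The generator emulates the data environment of a multi-temporal top-down
population mapping study in a data-scarce coastal region: nested admin
levels (coarse districts, fine sub-locations, finest enumeration areas),
built-up percentage grids at satellite epochs bracketing the census years,
time-invariant geography (land cover, elevation/slope, roads, rivers,
protected areas, a coastline), and per-year census tables that are exact
zonal aggregates of a known people-per-cell truth surface.

Truth density is log-linear in standardized log-scaled covariates with
per-census-year coefficients (letting the covariate-density relationship
drift across years), plus Gaussian noise on the log scale; zone totals
follow configured compound growth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import covariates as cov
from .model import build_exclusion_mask
from .raster import RasterGrid
from .zones import AdminZoneSet, grow_nested_zones, zonal_sum

log = logging.getLogger(__name__)

COARSE_LEVEL = 2  # emulates ADM-2 (district)
FINE_LEVEL = 5  # emulates ADM-5 (sub-location)
FINEST_LEVEL = 6  # emulates ADM-6 (enumeration area)


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    ``density_coefficients`` maps census year -> {covariate name -> float};
    a plain {name -> float} dict is broadcast to every census year (no
    drift).  Coefficients act on standardized log1p-scaled covariate layers,
    so their magnitudes are comparable across covariates.

    ``noise_sd`` is the cell-level Gaussian sd on the log-density scale.
    ``rural_density`` is the baseline people-per-cell in fully unsettled
    cells (before per-zone rescaling); populated rural areas exist even at
    zero built-up.  ``growth_rate`` is the mean annual compound growth of
    coarse-zone totals, jittered per zone by ``growth_jitter`` (sd).
    """

    grid_rows: int = 120
    grid_cols: int = 120
    cell_size: float = 100.0
    epochs: tuple[int, ...] = (1975, 1990, 2000, 2014)
    census_years: tuple[int, ...] = (1979, 1989, 1999, 2009)
    n_coarse_zones: int = 8
    n_fine_zones: int = 40
    n_finest_zones: int = 200
    density_coefficients: dict = field(
        default_factory=lambda: {
            cov.BUILTUP: 1.2,
            cov.DIST_ROADS: -0.3,
            "dist_cultivated": -0.15,
            cov.ELEVATION: -0.1,
        }
    )
    noise_sd: float = 0.3
    seed: int = 0
    domain_population: float = 1_000_000.0
    rural_density: float = 2.0
    growth_rate: float = 0.033
    growth_jitter: float = 0.0
    buffer_distance: float = 200.0
    exclude_buffers_in_truth: bool = True
    n_urban_centres: int = 3

    def __post_init__(self) -> None:
        self.epochs = tuple(self.epochs)
        self.census_years = tuple(self.census_years)
        if list(self.epochs) != sorted(set(self.epochs)):
            raise ValueError(f"epochs must be strictly increasing: {self.epochs}")
        lo, hi = min(self.epochs), max(self.epochs)
        bad = [y for y in self.census_years if not lo <= y <= hi]
        if bad:
            raise ValueError(f"census years {bad} outside epoch span [{lo}, {hi}]")
        if not (self.n_coarse_zones <= self.n_fine_zones <= self.n_finest_zones):
            raise ValueError(
                "zone counts must nest: "
                f"{self.n_coarse_zones} <= {self.n_fine_zones} <= {self.n_finest_zones}"
            )
        if self.n_coarse_zones < 1:
            raise ValueError("need at least one coarse zone")

    def coefficients_for(self, year: int) -> dict[str, float]:
        dc = self.density_coefficients
        if dc and all(isinstance(v, dict) for v in dc.values()):
            if year not in dc:
                raise KeyError(f"no density coefficients for census year {year}")
            return dict(dc[year])
        return dict(dc)


@dataclass
class SyntheticScene:
    """A generated landscape plus ground truth and census tables."""

    config: SceneConfig
    builtup_by_epoch: dict[int, RasterGrid]
    landcover: RasterGrid
    elevation: RasterGrid
    slope: RasterGrid
    road_mask: RasterGrid
    river_mask: RasterGrid
    protected_mask: RasterGrid
    coastline_mask: RasterGrid
    zones_by_level: dict[int, AdminZoneSet]
    truth_by_year: dict[int, RasterGrid]
    census_by_level_year: dict[tuple[int, int], pd.DataFrame]
    exclusion_mask: RasterGrid
    growth_rates: dict[int, float]

    @property
    def reference(self) -> RasterGrid:
        return self.landcover

    def stack_for_year(self, year: int, **kwargs) -> cov.CovariateStack:
        """Covariate stack for one census year, on the scene's grid."""
        return cov.build_stack(
            year=year,
            builtup_by_epoch=self.builtup_by_epoch,
            landcover=self.landcover,
            elevation=self.elevation,
            slope=self.slope,
            road_mask=self.road_mask,
            river_mask=self.river_mask,
            reference=self.reference,
            **kwargs,
        )


def recovery_scene_config(seed: int = 0, grid: int = 100) -> SceneConfig:
    """Drift-free scene with a strong built-up signal.

    The standard conditions for parameter-recovery experiments: density is
    driven chiefly by settlement, the covariate-density relationship is
    identical across census years, and moderate log-scale noise remains.
    """
    return SceneConfig(
        grid_rows=grid,
        grid_cols=grid,
        n_coarse_zones=6,
        n_fine_zones=30,
        n_finest_zones=120,
        density_coefficients={
            cov.BUILTUP: 1.5,
            cov.DIST_ROADS: -0.25,
            cov.ELEVATION: -0.1,
        },
        noise_sd=0.3,
        seed=seed,
    )


def drifted_scene_config(seed: int = 0, grid: int = 80) -> SceneConfig:
    """Four census years with relationship drift concentrated in the first.

    Emulates the regime where a covariate-density relationship differs in
    the year most distant from the detailed training data: the first year
    downweights settlement and flips the road/cultivated-land effects,
    while the later three share one stable relationship.
    """
    stable = {
        cov.BUILTUP: 1.2,
        cov.DIST_ROADS: -0.3,
        "dist_cultivated": -0.15,
        cov.ELEVATION: -0.1,
    }
    drifted = {
        cov.BUILTUP: 0.3,
        cov.DIST_ROADS: 0.6,
        "dist_cultivated": -0.8,
        cov.ELEVATION: -0.1,
    }
    years = (1979, 1989, 1999, 2009)
    return SceneConfig(
        grid_rows=grid,
        grid_cols=grid,
        n_coarse_zones=4,
        n_fine_zones=20,
        n_finest_zones=80,
        census_years=years,
        density_coefficients={years[0]: drifted, **{y: stable for y in years[1:]}},
        noise_sd=0.3,
        seed=seed,
    )


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def _polyline_mask(shape, rows: np.ndarray) -> np.ndarray:
    """One-cell-wide horizontal-ish line given a row index per column."""
    mask = np.zeros(shape, dtype=np.int16)
    cols = np.arange(shape[1])
    rows = np.clip(np.round(rows).astype(int), 0, shape[0] - 1)
    mask[rows, cols] = 1
    for c in range(1, shape[1]):  # fill vertical jumps to keep the line connected
        r0, r1 = sorted((rows[c - 1], rows[c]))
        mask[r0 : r1 + 1, c] = 1
    return mask


def _builtup_epochs(cfg: SceneConfig, rng: np.random.Generator) -> dict[int, RasterGrid]:
    """Urban cores that grow over epochs, as built-up percentage in [0, 100]."""
    shape = (cfg.grid_rows, cfg.grid_cols)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    centres = rng.uniform(0.1, 0.9, size=(cfg.n_urban_centres, 2))
    sigmas = rng.uniform(0.04, 0.10, size=cfg.n_urban_centres) * min(shape)
    amps = rng.uniform(40.0, 90.0, size=cfg.n_urban_centres)
    speckle = np.clip(_smooth_field(rng, shape, 2.0), 0, None) ** 2
    out: dict[int, RasterGrid] = {}
    e0 = cfg.epochs[0]
    for epoch in cfg.epochs:
        growth = (1.0 + 0.035) ** (epoch - e0)  # settlement expansion per year
        total = np.zeros(shape)
        for (fr, fc), s, a in zip(centres, sigmas, amps):
            d2 = (rr - fr * shape[0]) ** 2 + (cc - fc * shape[1]) ** 2
            total += a * growth * np.exp(-d2 / (2 * (s * np.sqrt(growth)) ** 2))
        total += 3.0 * growth * speckle
        out[epoch] = RasterGrid(
            np.clip(total, 0.0, 100.0), cell_size=cfg.cell_size
        )
    return out


def _standardize_log(values: np.ndarray, where: np.ndarray) -> np.ndarray:
    z = np.log1p(np.maximum(values, 0.0))
    mu, sd = z[where].mean(), z[where].std()
    return (z - mu) / (sd + 1e-12)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a complete seeded scene; identical config => identical scene."""
    cfg = config
    shape = (cfg.grid_rows, cfg.grid_cols)
    ss = np.random.SeedSequence(cfg.seed)
    (s_zone, s_land, s_elev, s_bu, s_lines, s_prot, s_growth, s_noise) = [
        np.random.default_rng(c) for c in ss.spawn(8)
    ]

    zones = grow_nested_zones(
        shape,
        {
            COARSE_LEVEL: cfg.n_coarse_zones,
            FINE_LEVEL: cfg.n_fine_zones,
            FINEST_LEVEL: cfg.n_finest_zones,
        },
        s_zone,
        cell_size=cfg.cell_size,
    )

    lc_field = _smooth_field(s_land, shape, sigma=min(shape) / 12)
    breaks = np.quantile(lc_field, [0.25, 0.45, 0.60, 0.75, 0.85, 0.90, 0.95, 0.99])
    landcover = RasterGrid(
        (np.digitize(lc_field, breaks) + 1).astype(np.int16), cell_size=cfg.cell_size
    )

    elev_vals = 250.0 + 180.0 * _smooth_field(s_elev, shape, sigma=min(shape) / 8)
    elevation = RasterGrid(np.maximum(elev_vals, 0.0), cell_size=cfg.cell_size)
    gy, gx = np.gradient(elevation.values, cfg.cell_size)
    slope = RasterGrid(np.degrees(np.arctan(np.hypot(gy, gx))), cell_size=cfg.cell_size)

    builtup = _builtup_epochs(cfg, s_bu)

    cols = np.arange(cfg.grid_cols)
    road_rows = (
        cfg.grid_rows * 0.5
        + cfg.grid_rows * 0.15 * np.sin(2 * np.pi * cols / cfg.grid_cols + s_lines.uniform(0, 2 * np.pi))
    )
    road_mask = RasterGrid(_polyline_mask(shape, road_rows), cell_size=cfg.cell_size)
    river_rows = (
        cfg.grid_rows * 0.25
        + cfg.grid_rows * 0.1 * np.sin(4 * np.pi * cols / cfg.grid_cols + s_lines.uniform(0, 2 * np.pi))
    )
    river_mask = RasterGrid(_polyline_mask(shape, river_rows), cell_size=cfg.cell_size)

    coast = np.zeros(shape, dtype=np.int16)
    coast[:, -1] = 1  # eastern seaboard
    coastline_mask = RasterGrid(coast, cell_size=cfg.cell_size)

    protected = np.zeros(shape, dtype=np.int16)
    for _ in range(3):
        h = s_prot.integers(cfg.grid_rows // 12, cfg.grid_rows // 6)
        w = s_prot.integers(cfg.grid_cols // 12, cfg.grid_cols // 6)
        r0 = s_prot.integers(0, cfg.grid_rows - h)
        c0 = s_prot.integers(0, cfg.grid_cols - w)
        protected[r0 : r0 + h, c0 : c0 + w] = 1
    protected_mask = RasterGrid(protected, cell_size=cfg.cell_size)

    exclusion = build_exclusion_mask(
        protected_mask, road_mask, coastline_mask, buffer_distance=cfg.buffer_distance
    )
    truth_zero = (
        exclusion.values.astype(bool)
        if cfg.exclude_buffers_in_truth
        else protected_mask.values.astype(bool)
    )
    habitable = ~truth_zero

    coarse = zones[COARSE_LEVEL]
    coarse_ids = [int(z) for z in coarse.zone_ids]
    growth_rates = {
        zid: float(cfg.growth_rate + cfg.growth_jitter * s_growth.standard_normal())
        for zid in coarse_ids
    }

    # raw (unscaled) log-linear density per census year
    y0 = min(cfg.census_years)
    base_totals: dict[int, float] | None = None
    truth_by_year: dict[int, RasterGrid] = {}
    noise_rngs = {y: np.random.default_rng(c) for y, c in zip(cfg.census_years, s_noise.spawn(len(cfg.census_years)))}
    for year in sorted(cfg.census_years):
        coeffs = cfg.coefficients_for(year)
        log_density = np.full(shape, np.log(cfg.rural_density))
        if coeffs:
            layer_source = _covariate_layers_for_truth(
                cfg, year, builtup, landcover, elevation, slope, road_mask, river_mask
            )
            for name, coef in coeffs.items():
                if name not in layer_source:
                    raise KeyError(f"unknown density covariate {name!r}")
                log_density += coef * _standardize_log(layer_source[name], habitable)
        if cfg.noise_sd > 0:
            log_density += cfg.noise_sd * noise_rngs[year].standard_normal(shape)
        raw = np.where(habitable, np.exp(log_density), 0.0)

        raw_sums = zonal_sum(RasterGrid(raw, cell_size=cfg.cell_size), coarse)
        if base_totals is None:
            scale0 = cfg.domain_population / raw_sums.sum()
            base_totals = {int(z): float(raw_sums[z] * scale0) for z in coarse_ids}
        people = np.zeros(shape)
        for zid in coarse_ids:
            target = base_totals[zid] * (1.0 + growth_rates[zid]) ** (year - y0)
            zsum = raw_sums[zid]
            sel = coarse.cells_of(zid)
            if zsum <= 0:
                habitable_sel = sel & habitable
                n = habitable_sel.sum()
                if n:
                    people[habitable_sel] = target / n
                continue
            people[sel] = raw[sel] * (target / zsum)
        truth_by_year[year] = RasterGrid(people, cell_size=cfg.cell_size)

    census: dict[tuple[int, int], pd.DataFrame] = {}
    for level, zset in zones.items():
        for year, truth in truth_by_year.items():
            census[(level, year)] = aggregate_truth(truth, zset, level=level, year=year)

    return SyntheticScene(
        config=cfg,
        builtup_by_epoch=builtup,
        landcover=landcover,
        elevation=elevation,
        slope=slope,
        road_mask=road_mask,
        river_mask=river_mask,
        protected_mask=protected_mask,
        coastline_mask=coastline_mask,
        zones_by_level=zones,
        truth_by_year=truth_by_year,
        census_by_level_year=census,
        exclusion_mask=exclusion,
        growth_rates=growth_rates,
    )


def _covariate_layers_for_truth(
    cfg: SceneConfig, year, builtup, landcover, elevation, slope, road_mask, river_mask
) -> dict[str, np.ndarray]:
    """Raw covariate arrays the truth model may reference by name."""
    t1, t2 = cov.select_bracketing_epochs(year, list(builtup))
    bu = cov.interpolate_builtup(
        cov.InterpolationSpec(year, t1, t2, builtup[t1], builtup[t2])
    )
    layers: dict[str, np.ndarray] = {
        cov.BUILTUP: bu.values,
        cov.ELEVATION: elevation.values,
        cov.SLOPE: slope.values,
        cov.DIST_ROADS: cov.distance_to_class(road_mask, {1}).values,
        cov.DIST_RIVERS: cov.distance_to_class(river_mask, {1}).values,
    }
    for code, name in cov.DEFAULT_LC_CLASSES.items():
        if (landcover.values == code).any():
            layers[f"dist_{name}"] = cov.distance_to_class(landcover, {code}).values
    return layers


def aggregate_truth(
    truth: RasterGrid, zones: AdminZoneSet, level: int | None = None, year: int = 0
) -> pd.DataFrame:
    """Exact zonal sums of a truth surface -> census table.

    Returns a DataFrame with columns zone_id, level, year, population, area;
    counts sum to the domain total.  A zone with no cells raises.
    """
    sums = zonal_sum(truth, zones)
    counts = zones.zone_cell_counts()
    empty = counts.index[counts == 0]
    if len(empty):
        raise ValueError(f"zone {int(empty[0])} has no cells")
    return pd.DataFrame(
        {
            "zone_id": sums.index.to_numpy(),
            "level": level if level is not None else zones.level,
            "year": year,
            "population": sums.to_numpy(),
            "area": counts.reindex(sums.index).to_numpy() * truth.cell_area,
        }
    )


def integerize_census(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Largest-remainder rounding of populations to integers.

    Preserves the (rounded) total; offered for realism — the generator's
    native tables are real-valued so conservation invariants hold exactly.
    """
    out = table.copy()
    pop = out["population"].to_numpy(float)
    floors = np.floor(pop)
    short = int(round(pop.sum())) - int(floors.sum())
    order = np.argsort(-(pop - floors), kind="stable")
    add = np.zeros_like(floors)
    add[order[:short]] = 1
    out["population"] = floors + add
    return out
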
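"""M1/M2 training-scheme comparison and reaggregation validation.

Two ways of fitting density models across census years are compared:

* **M1** — one model, trained on the single year with the most spatially
  detailed census data (e.g. enumeration-area level), transferred to every
  year through that year's covariate stack.  Assumes covariate–density
  relationships are stable in time.
* **M2** — an independent model per census year, trained on that year's own
  (coarser) census data, so relationship drift is absorbed.

Both schemes redistribute coarse-level (district) counts, and are scored by
summing the gridded predictions within held fine-level units and comparing
to the fine-level census via RMSE and MAE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DasymetricModel, PopulationSurface, dasymetric_redistribute
from .zones import AdminZoneSet, aggregate_census_upward, zonal_sum

log = logging.getLogger(__name__)

#: Published total de facto population of the Kenyan coastal districts
#: (Kilifi, Malindi, Mombasa, Kwale) per census year — the motivating
#: real-world growth series.
KENYA_COAST_TOTALS: dict[int, int] = {
    1979: 1_014_567,
    1989: 1_444_296,
    1999: 1_949_264,
    2009: 2_679_478,
}


@dataclass
class SchemeSpec:
    """Which scheme to run and at which admin levels.

    ``redistribution_level`` (coarse, district-like) must be strictly
    coarser (smaller number) than ``evaluation_level``; M1 additionally
    needs a ``training_year`` with data at ``training_level``.
    """

    scheme: str
    years: tuple[int, ...]
    training_level: int
    evaluation_level: int
    redistribution_level: int
    training_year: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in {"M1", "M2"}:
            raise ValueError(f"scheme must be 'M1' or 'M2', got {self.scheme!r}")
        if not self.redistribution_level < self.evaluation_level:
            raise ValueError(
                "redistribution level must be strictly coarser than evaluation level"
            )
        if self.scheme == "M1" and self.training_year is None:
            raise ValueError("M1 requires a training_year")


@dataclass
class ValidationReport:
    """Per (scheme, year) accuracy of reaggregated predictions."""

    entries: pd.DataFrame  # scheme, year, rmse, mae, n_units
    residuals: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)

    def metric(self, scheme: str, year: int, name: str) -> float:
        e = self.entries
        row = e[(e["scheme"] == scheme) & (e["year"] == year)]
        if row.empty:
            raise KeyError((scheme, year))
        return float(row[name].iloc[0])


def _coarse_census(scene, spec: SchemeSpec, year: int) -> pd.DataFrame:
    """Coarse counts derived by aggregating the evaluation-level census
    upward, guaranteeing that predicted and observed coarse totals agree."""
    fine = scene.zones_by_level[spec.evaluation_level]
    table = scene.census_by_level_year[(spec.evaluation_level, year)]
    out = table
    level = spec.evaluation_level
    zones = fine
    while level > spec.redistribution_level:
        parent_level = max(
            lv for lv in scene.zones_by_level if lv < level
        )
        out = aggregate_census_upward(out, zones, parent_level)
        zones = scene.zones_by_level[parent_level]
        level = parent_level
    return out


def run_m1(
    scene,
    spec: SchemeSpec,
    stacks: dict[int, object] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> dict[int, PopulationSurface]:
    """One model fitted at (training_year, training_level), applied to all
    years through their own covariate stacks."""
    stacks = stacks or {y: scene.stack_for_year(y) for y in spec.years}
    missing = [y for y in spec.years if y not in stacks]
    if missing:
        raise ValueError(f"missing covariate stacks for years {missing}")
    results = DasymetricModel.from_scene(
        scene,
        spec.training_year,
        spec.training_level,
        stack=stacks.get(spec.training_year) or scene.stack_for_year(spec.training_year),
        n_trees=n_trees,
        seed=seed,
    ).fit()
    coarse_zones = scene.zones_by_level[spec.redistribution_level]
    out: dict[int, PopulationSurface] = {}
    for year in spec.years:
        weights = results.predict_weight_surface(stacks[year], scene.exclusion_mask)
        out[year] = dasymetric_redistribute(
            weights,
            coarse_zones,
            _coarse_census(scene, spec, year),
            provenance={"scheme": "M1", "year": year},
        )
    return out


def run_m2(
    scene,
    spec: SchemeSpec,
    stacks: dict[int, object] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> dict[int, PopulationSurface]:
    """Year-specific models: each year trains on its own census at
    training_level and predicts its own weights.  Per-year forests draw
    from a shared seed stream (seed + year offset) for reproducibility
    without coupling."""
    stacks = stacks or {y: scene.stack_for_year(y) for y in spec.years}
    missing = [y for y in spec.years if y not in stacks]
    if missing:
        raise ValueError(f"missing covariate stacks for years {missing}")
    coarse_zones = scene.zones_by_level[spec.redistribution_level]
    out: dict[int, PopulationSurface] = {}
    for i, year in enumerate(sorted(spec.years)):
        results = DasymetricModel.from_scene(
            scene,
            year,
            spec.training_level,
            stack=stacks[year],
            n_trees=n_trees,
            seed=seed + i,
        ).fit()
        weights = results.predict_weight_surface(stacks[year], scene.exclusion_mask)
        out[year] = dasymetric_redistribute(
            weights,
            coarse_zones,
            _coarse_census(scene, spec, year),
            provenance={"scheme": "M2", "year": year},
        )
    return out


def validate_by_reaggregation(
    surface: PopulationSurface,
    reference_zones: AdminZoneSet,
    reference_census: pd.DataFrame,
) -> dict:
    """Sum the surface within each reference zone and score against census.

    Returns rmse, mae, n_units and the per-zone residual table
    (predicted - observed).
    """
    predicted = zonal_sum(surface.people_per_cell, reference_zones)
    obs = reference_census.set_index("zone_id")["population"]
    missing = set(obs.index) - set(predicted.index)
    extra = set(predicted.index) - set(obs.index)
    if missing or extra:
        raise ValueError(
            f"zone mismatch between surface and census: missing={sorted(missing)[:5]} "
            f"extra={sorted(extra)[:5]}"
        )
    resid = (predicted.reindex(obs.index) - obs).rename("residual")
    rmse = float(np.sqrt(np.mean(resid.to_numpy() ** 2)))
    mae = float(np.mean(np.abs(resid.to_numpy())))
    return {
        "rmse": rmse,
        "mae": mae,
        "n_units": int(len(resid)),
        "residuals": resid.reset_index(),
    }


def score_schemes(
    scene,
    surfaces_by_scheme: dict[str, dict[int, PopulationSurface]],
    evaluation_level: int,
) -> ValidationReport:
    """Build a ValidationReport for several schemes over their years."""
    zones = scene.zones_by_level[evaluation_level]
    rows, residuals = [], {}
    for scheme, by_year in surfaces_by_scheme.items():
        for year, surface in by_year.items():
            census = scene.census_by_level_year[(evaluation_level, year)]
            entry = validate_by_reaggregation(surface, zones, census)
            rows.append(
                {
                    "scheme": scheme,
                    "year": year,
                    "rmse": entry["rmse"],
                    "mae": entry["mae"],
                    "n_units": entry["n_units"],
                }
            )
            residuals[(scheme, year)] = entry["residuals"]
    return ValidationReport(pd.DataFrame(rows), residuals)


def compare_schemes(report: ValidationReport) -> pd.DataFrame:
    """Per-year winner per metric, with a disagreement flag.

    Requires both schemes scored on identical year sets; ties yield the
    winner ``'tie'`` and set the flag.
    """
    e = report.entries
    schemes = sorted(e["scheme"].unique())
    if len(schemes) != 2:
        raise ValueError(f"need exactly two schemes, got {schemes}")
    a, b = schemes
    years_a = set(e.loc[e["scheme"] == a, "year"])
    years_b = set(e.loc[e["scheme"] == b, "year"])
    if years_a != years_b:
        raise ValueError(f"unmatched year sets: {sorted(years_a)} vs {sorted(years_b)}")
    rows = []
    for year in sorted(years_a):
        winners = {}
        for metric in ("rmse", "mae"):
            va = report.metric(a, year, metric)
            vb = report.metric(b, year, metric)
            winners[metric] = "tie" if va == vb else (a if va < vb else b)
        rows.append(
            {
                "year": year,
                "rmse_winner": winners["rmse"],
                "mae_winner": winners["mae"],
                "metrics_disagree": winners["rmse"] != winners["mae"],
            }
        )
    return pd.DataFrame(rows)


def growth_summary(
    census_by_year: dict[int, pd.DataFrame] | dict[int, float]
) -> pd.DataFrame:
    """Totals, last/first ratio and average annual compound growth rate.

    Accepts either census tables per year or plain totals per year.
    ``r = (P_last / P_first) ** (1 / (y_last - y_first)) - 1``; a zero
    first-year total leaves ratio and rate as NaN with a flag.

    Returns one row per zone plus a ``'domain'`` row with columns
    first_total, last_total, ratio, annual_rate, undefined; per-year domain
    totals are attached as ``.attrs['totals']``.
    """
    years = sorted(census_by_year)
    if len(years) < 2:
        raise ValueError("need at least two census years")
    span = years[-1] - years[0]

    def _series(v) -> pd.Series:
        if isinstance(v, pd.DataFrame):
            return v.set_index("zone_id")["population"].astype(float)
        return pd.Series({"domain": float(v)})

    first = _series(census_by_year[years[0]])
    last = _series(census_by_year[years[-1]])
    rows = []
    units = list(first.index)
    if "domain" not in units:
        units.append("domain")
    for zid in units:
        p0 = float(first.get(zid, first.sum() if zid == "domain" else np.nan))
        p1 = float(last.get(zid, last.sum() if zid == "domain" else np.nan))
        undefined = not p0 > 0
        ratio = np.nan if undefined else p1 / p0
        rate = np.nan if undefined else ratio ** (1.0 / span) - 1.0
        if undefined:
            log.warning("growth_summary: zone %s has zero first-year total", zid)
        rows.append(
            {
                "zone_id": zid,
                "first_total": p0,
                "last_total": p1,
                "ratio": ratio,
                "annual_rate": rate,
                "undefined": undefined,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["totals"] = {
        y: float(_series(census_by_year[y]).sum()) for y in years
    }
    return out


def plot_report(report: ValidationReport, path: str) -> None:
    """RMSE/MAE per scheme and year as a grouped bar chart (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    e = report.entries
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, metric in zip(axes, ("rmse", "mae")):
        pivot = e.pivot(index="year", columns="scheme", values=metric)
        pivot.plot.bar(ax=ax, rot=0)
        ax.set_ylabel(metric.upper())
        ax.set_xlabel("census year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
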
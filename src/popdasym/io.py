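"""Readers and writers shared by all pipeline stages.

Rasters travel as single-band ESRI ASCII grids (``.asc``): a plain-text
header (ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value)
followed by the cell values, integer layers written as integers.  Zones
travel as GeoJSON polygon FeatureCollections with ``zone_id``,
``parent_id`` and ``level`` properties; census tables as CSV with header
``zone_id,level,year,population[,area]``; configs as YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .raster import RasterGrid
from .zones import AdminZoneSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------- #
# rasters


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a single-band ASCII grid; integer arrays stay integer."""
    path = Path(path)
    vals = np.asarray(grid.values)
    is_int = np.issubdtype(vals.dtype, np.integer)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {int(grid.nodata) if is_int else grid.nodata!r}\n"
    )
    fmt = "%d" if is_int else "%.17e"  # %e keeps a float marker for re-reading
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ASCII grid written by :func:`write_raster` (or compatible)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    header: dict[str, float] = {}
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, _, val = line.partition(" ")
        key = key.strip().lower()
        if key not in keys:
            raise ValueError(f"unreadable raster header in {path}: {line!r}")
        header[key] = float(val)
    if len(header) != 6:
        raise ValueError(f"incomplete raster header in {path}")
    body = " ".join(lines[6:])
    is_int = not any(ch in body for ch in ".eE")
    vals = np.array(body.split(), dtype=float)
    vals = vals.reshape(int(header["nrows"]), int(header["ncols"]))
    if is_int:
        vals = vals.astype(np.int32)
    return RasterGrid(
        vals,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header["nodata_value"],
    )


# ---------------------------------------------------------------------- #
# zones


def _zone_polygon(labels: np.ndarray, zone_id: int, grid: RasterGrid):
    """Union of per-row cell runs — far fewer geometries than per-cell boxes."""
    rects = []
    n_rows = labels.shape[0]
    for r in range(n_rows):
        row = labels[r] == zone_id
        if not row.any():
            continue
        (cols,) = np.nonzero(row)
        splits = np.split(cols, np.where(np.diff(cols) != 1)[0] + 1)
        y_top = grid.origin_y + (n_rows - r) * grid.cell_size
        y_bot = y_top - grid.cell_size
        for run in splits:
            x0 = grid.origin_x + run[0] * grid.cell_size
            x1 = grid.origin_x + (run[-1] + 1) * grid.cell_size
            rects.append(box(x0, y_bot, x1, y_top))
    return unary_union(rects)


def write_zones(zones: AdminZoneSet, path: str | Path) -> None:
    """Write zones as a GeoJSON FeatureCollection of polygons."""
    grid = zones.labels
    features = []
    for zid in zones.zone_ids:
        poly = _zone_polygon(grid.values, int(zid), grid)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "zone_id": int(zid),
                    "parent_id": None
                    if zones.parents is None
                    else int(zones.parents[int(zid)]),
                    "level": zones.level,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_zones(path: str | Path, reference: RasterGrid) -> AdminZoneSet:
    """Read GeoJSON zones and rasterize onto the reference grid.

    A cell belongs to the zone containing its centre; centres on shared
    edges go to the zone with the smaller zone_id (first-winner in
    ascending id order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"zones not found: {path}")
    with open(path) as fh:
        fc = json.load(fh)
    feats = fc.get("features", [])
    if not feats:
        raise ValueError(f"no features in {path}")
    levels = {f["properties"]["level"] for f in feats}
    if len(levels) != 1:
        raise ValueError(f"mixed admin levels in one zone file: {sorted(levels)}")
    ids = [f["properties"]["zone_id"] for f in feats]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate zone_id in {path}")

    x, y = reference.cell_centres()
    labels = np.zeros(reference.shape, dtype=np.int32)
    parents: dict[int, int] = {}
    has_parents = False
    for f in sorted(feats, key=lambda f: f["properties"]["zone_id"]):
        zid = int(f["properties"]["zone_id"])
        pid = f["properties"].get("parent_id")
        if pid is not None:
            parents[zid] = int(pid)
            has_parents = True
        geom = shape(f["geometry"])
        unset = labels == 0
        hit = shapely.intersects_xy(geom, x, y) & unset
        labels[hit] = zid
    if (labels == 0).any():
        raise ValueError(
            f"{int((labels == 0).sum())} cells of the reference grid fall in no zone"
        )
    return AdminZoneSet(
        reference.with_values(labels),
        level=int(levels.pop()),
        parents=parents if has_parents else None,
    )


# ---------------------------------------------------------------------- #
# census tables


def write_census(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["zone_id", "level", "year", "population"] + (
        ["area"] if "area" in table.columns else []
    )
    table[cols].to_csv(path, index=False)


def read_census(
    path: str | Path, zones: AdminZoneSet | None = None
) -> pd.DataFrame:
    """Read and validate a census CSV; optionally cross-check zone ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"census not found: {path}")
    df = pd.read_csv(path)
    required = {"zone_id", "level", "year", "population"}
    missing = required - set(df.columns)
    errors = []
    if missing:
        raise ValueError(f"census {path} missing columns {sorted(missing)}")
    if (df["population"] < 0).any():
        bad = df.loc[df["population"] < 0, "zone_id"].tolist()
        errors.append(f"negative population for zones {bad[:5]}")
    dup = df.duplicated(subset=["zone_id", "level", "year"])
    if dup.any():
        errors.append(
            f"duplicate (zone_id, level, year) rows: {df.loc[dup, 'zone_id'].tolist()[:5]}"
        )
    if zones is not None:
        level = zones.level
        known = set(int(z) for z in zones.zone_ids)
        sub = df[df["level"] == level]
        unknown = set(sub["zone_id"].astype(int)) - known
        if unknown:
            errors.append(f"census references absent zones {sorted(unknown)[:5]}")
    if errors:
        raise ValueError("; ".join(errors))
    return df


# ---------------------------------------------------------------------- #
# config + scene directories


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


_MASK_LAYERS = (
    "landcover",
    "elevation",
    "slope",
    "road_mask",
    "river_mask",
    "protected_mask",
    "coastline_mask",
    "exclusion_mask",
)


def save_scene(scene, out_dir: str | Path) -> list[Path]:
    """Serialize a scene to a directory of .asc/.geojson/.csv/.yaml files."""
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cfg = asdict(scene.config)
    cfg["epochs"] = list(cfg["epochs"])
    cfg["census_years"] = list(cfg["census_years"])
    write_config(cfg, out / "config.yaml")
    written.append(out / "config.yaml")

    for epoch, grid in scene.builtup_by_epoch.items():
        p = out / f"builtup_{epoch}.asc"
        write_raster(grid, p)
        written.append(p)
    for name in _MASK_LAYERS:
        p = out / f"{name}.asc"
        write_raster(getattr(scene, name), p)
        written.append(p)
    for year, truth in scene.truth_by_year.items():
        p = out / f"truth_{year}.asc"
        write_raster(truth, p)
        written.append(p)
    for level, zset in scene.zones_by_level.items():
        p = out / f"zones_level{level}.geojson"
        write_zones(zset, p)
        written.append(p)
    census = pd.concat(scene.census_by_level_year.values(), ignore_index=True)
    write_census(census, out / "census.csv")
    written.append(out / "census.csv")
    return written


def load_scene(scene_dir: str | Path):
    """Reconstruct a scene from a directory written by :func:`save_scene`."""
    from .scene import SceneConfig, SyntheticScene

    d = Path(scene_dir)
    cfg_dict = read_config(d / "config.yaml")
    cfg = SceneConfig(**cfg_dict)
    layers = {name: read_raster(d / f"{name}.asc") for name in _MASK_LAYERS}
    builtup = {e: read_raster(d / f"builtup_{e}.asc") for e in cfg.epochs}
    truth = {y: read_raster(d / f"truth_{y}.asc") for y in cfg.census_years}
    reference = layers["landcover"]
    zones = {}
    for p in sorted(d.glob("zones_level*.geojson")):
        zset = read_zones(p, reference)
        zones[zset.level] = zset
    census_all = read_census(d / "census.csv")
    census = {
        (int(level), int(year)): sub.reset_index(drop=True)
        for (level, year), sub in census_all.groupby(["level", "year"])
    }
    return SyntheticScene(
        config=cfg,
        builtup_by_epoch=builtup,
        landcover=layers["landcover"],
        elevation=layers["elevation"],
        slope=layers["slope"],
        road_mask=layers["road_mask"],
        river_mask=layers["river_mask"],
        protected_mask=layers["protected_mask"],
        coastline_mask=layers["coastline_mask"],
        zones_by_level=zones,
        truth_by_year=truth,
        census_by_level_year=census,
        exclusion_mask=layers["exclusion_mask"],
        growth_rates={},
    )
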
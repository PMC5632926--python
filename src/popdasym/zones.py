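"""Administrative zone partitions on the common grid.

An :class:`AdminZoneSet` is a label raster assigning every cell to exactly one
zone of one admin level, plus a parent map linking each zone to its containing
zone at the next coarser level.  Hierarchies are strictly nested: every fine
zone lies inside exactly one coarse zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid, check_coregistered


@dataclass
class AdminZoneSet:
    """Partition of the domain at one admin level.

    Parameters
    ----------
    labels : RasterGrid
        Integer grid; each cell holds the id of the zone that contains its
        centre.  Zone ids are positive integers, unique within the level.
    level : int
        Admin level (larger = finer, following ADM-n numbering).
    parents : dict[int, int] | None
        zone_id -> parent zone_id at the next coarser level; None at the
        coarsest level in play.
    """

    labels: RasterGrid
    level: int
    parents: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.labels.values = np.asarray(self.labels.values, dtype=np.int32)

    @property
    def zone_ids(self) -> np.ndarray:
        return np.unique(self.labels.values)

    @property
    def n_zones(self) -> int:
        return self.zone_ids.size

    def cells_of(self, zone_id: int) -> np.ndarray:
        return self.labels.values == zone_id

    def zone_cell_counts(self) -> pd.Series:
        ids, counts = np.unique(self.labels.values, return_counts=True)
        return pd.Series(counts, index=pd.Index(ids, name="zone_id"), name="n_cells")

    def check_nesting(self, coarser: "AdminZoneSet") -> None:
        """Verify each of this level's zones lies inside one coarser zone."""
        check_coregistered(self.labels, coarser.labels)
        fine = self.labels.values.ravel()
        coarse = coarser.labels.values.ravel()
        df = pd.DataFrame({"fine": fine, "coarse": coarse})
        n_parents = df.groupby("fine")["coarse"].nunique()
        bad = n_parents[n_parents > 1]
        if len(bad):
            raise ValueError(
                f"zones {list(bad.index[:5])} at level {self.level} straddle "
                f"multiple level-{coarser.level} zones"
            )


def zonal_sum(surface: RasterGrid, zones: AdminZoneSet) -> pd.Series:
    """Sum of ``surface`` values over each zone (nodata treated as 0)."""
    check_coregistered(surface, zones.labels)
    vals = np.where(surface.valid_mask(), surface.values, 0.0).ravel()
    labels = zones.labels.values.ravel()
    sums = np.bincount(labels, weights=vals)
    ids = zones.zone_ids
    return pd.Series(sums[ids], index=pd.Index(ids, name="zone_id"), name="sum")


def grow_nested_zones(
    shape: tuple[int, int],
    counts: dict[int, int],
    rng: np.random.Generator,
    cell_size: float = 100.0,
) -> dict[int, AdminZoneSet]:
    """Build a nested admin hierarchy by seeded Voronoi subdivision.

    ``counts`` maps level -> number of zones, coarsest first; each level's
    zones are formed by Voronoi-partitioning every parent zone around seed
    cells drawn inside it, which guarantees strict nesting by construction.

    Returns level -> AdminZoneSet with globally unique zone ids per level.
    """
    levels = sorted(counts)
    if any(counts[a] > counts[b] for a, b in zip(levels, levels[1:])):
        raise ValueError(f"zone counts must be non-decreasing with level: {counts}")
    n_rows, n_cols = shape
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    out: dict[int, AdminZoneSet] = {}
    parent_labels = np.ones(shape, dtype=np.int32)  # virtual root
    parent_ids = [1]
    parent_level = None
    for level in levels:
        n_target = counts[level]
        # allocate children per parent: proportional to area, >= 1, largest remainder
        areas = np.array([(parent_labels == pid).sum() for pid in parent_ids], float)
        quota = np.maximum(1, np.floor(n_target * areas / areas.sum()).astype(int))
        while quota.sum() < n_target:
            quota[np.argmax(areas / quota)] += 1
        while quota.sum() > n_target:
            can = quota > 1
            idx = np.argmin(np.where(can, areas / quota, np.inf))
            quota[idx] -= 1
        labels = np.zeros(shape, dtype=np.int32)
        parents: dict[int, int] = {}
        next_id = 1
        for pid, k in zip(parent_ids, quota):
            inside = parent_labels == pid
            rows, cols = rr[inside], cc[inside]
            pick = rng.choice(rows.size, size=min(int(k), rows.size), replace=False)
            seeds_r, seeds_c = rows[pick], cols[pick]
            d2 = (rows[:, None] - seeds_r[None, :]) ** 2 + (
                cols[:, None] - seeds_c[None, :]
            ) ** 2
            assign = np.argmin(d2, axis=1)
            for j in range(seeds_r.size):
                sel = assign == j
                labels[rows[sel], cols[sel]] = next_id
                parents[next_id] = pid
                next_id += 1
        zone_set = AdminZoneSet(
            RasterGrid(labels, cell_size=cell_size),
            level=level,
            parents=None if parent_level is None else parents,
        )
        out[level] = zone_set
        parent_labels = labels
        parent_ids = list(range(1, next_id))
        parent_level = level
    return out


def aggregate_census_upward(
    census: pd.DataFrame, fine: AdminZoneSet, to_level: int
) -> pd.DataFrame:
    """Aggregate a fine-level census table to a coarser level via parent ids."""
    if fine.parents is None:
        raise ValueError(f"level {fine.level} has no parent mapping")
    df = census.copy()
    df["zone_id"] = df["zone_id"].map(fine.parents)
    if df["zone_id"].isna().any():
        raise ValueError("census contains zone ids missing from the zone set")
    out = (
        df.groupby(["zone_id", "year"], as_index=False)
        .agg(population=("population", "sum"), area=("area", "sum"))
        .assign(level=to_level)
    )
    return out[["zone_id", "level", "year", "population", "area"]]
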
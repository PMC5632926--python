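"""Planar single-band raster grid.

All layers in a scene share one planar grid: ``n_rows x n_cols`` square cells
of side ``cell_size`` (abstract metres), anchored at the lower-left corner
``(origin_x, origin_y)``.  Row 0 is the *top* row, matching array order.
Geographic CRS handling is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band grid of float or integer cell values.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values; ``nodata`` marks invalid cells.
    origin_x, origin_y : float
        Coordinates of the lower-left corner of the grid.
    cell_size : float
        Side length of a square cell, in abstract metres (> 0).
    nodata : float
        Sentinel for missing cells.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 100.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got shape {self.values.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        vals = self.values
        if np.issubdtype(vals.dtype, np.floating):
            return ~(np.isclose(vals, self.nodata) | np.isnan(vals))
        return vals != int(self.nodata)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """New grid with the same geometry but different values."""
        return replace(self, values=np.asarray(values))

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of cell centres, each shaped like values."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        # row 0 is the top row
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)


def check_coregistered(*grids: RasterGrid) -> None:
    """Raise ValueError unless all grids share one geometry."""
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise ValueError(
                "grids are not co-registered: "
                f"{ref.shape}@({ref.origin_x},{ref.origin_y},{ref.cell_size}) vs "
                f"{g.shape}@({g.origin_x},{g.origin_y},{g.cell_size})"
            )


def resample_nearest(grid: RasterGrid, reference: RasterGrid) -> RasterGrid:
    """Nearest-neighbour resample of ``grid`` onto the geometry of ``reference``.

    Each reference cell takes the value of the source cell containing its
    centre; centres outside the source extent become nodata.  Resampling a
    grid onto its own geometry is the identity.
    """
    if grid.same_geometry(reference):
        return RasterGrid(
            grid.values.copy(),
            reference.origin_x,
            reference.origin_y,
            reference.cell_size,
            grid.nodata,
        )
    x, y = reference.cell_centres()
    col = np.floor((x - grid.origin_x) / grid.cell_size).astype(int)
    row_from_bottom = np.floor((y - grid.origin_y) / grid.cell_size).astype(int)
    row = grid.n_rows - 1 - row_from_bottom
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    out = np.full(reference.shape, grid.nodata, dtype=np.asarray(grid.values).dtype)
    out[inside] = grid.values[row[inside], col[inside]]
    return RasterGrid(
        out, reference.origin_x, reference.origin_y, reference.cell_size, grid.nodata
    )
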
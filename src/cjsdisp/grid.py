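"""Discrete spatial support for the dispersal model.

The study landscape is a rectangular grid of square cells. Each cell carries
a plot-type label (``intensive``, ``auxiliary`` or ``unsampled``), a per-year
binary effort indicator ``s[k, t]`` (was the cell surveyed that year?), and a
single standardized climate score ``c_k`` obtained as the first principal
component of mean May temperature and precipitation normals.

Coordinates are planar (projected) meters; pairwise distances between cell
centers are Euclidean and reported in kilometers, the scale on which the
distance-decay parameter of the dispersal kernel is defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "PLOT_TYPES",
    "StudyGrid",
    "ClimateSurface",
    "build_grid",
    "climate_pc",
    "snap_to_cell",
]

PLOT_TYPES = ("intensive", "auxiliary", "unsampled")


@dataclass(frozen=True)
class ClimateSurface:
    """Standardized climate score per grid cell.

    ``score`` is the first principal component of (standardized) temperature
    and precipitation, sign-fixed so the temperature loading is positive:
    larger scores mean hotter and drier cells. Scores keep the raw PC1 scale
    of standardized inputs (they are not re-standardized), so the climate
    effect ``beta2`` of the kernel is interpreted per unit of that score.
    """

    score: np.ndarray
    loadings: np.ndarray  # (temperature, precipitation) weights on PC1
    variance_explained: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "score", np.asarray(self.score, dtype=float))
        object.__setattr__(self, "loadings", np.asarray(self.loadings, dtype=float))
        if not np.all(np.isfinite(self.score)):
            raise ValueError("climate score contains non-finite values")
        # sign convention: larger score = hotter/drier. The loading can be
        # exactly zero only in the degenerate equal-eigenvalue (uncorrelated)
        # case, where PC1 is arbitrary.
        if self.loadings[0] < 0:
            raise ValueError("temperature loading must be non-negative")


@dataclass
class StudyGrid:
    """Discretized study area: cells, distances, effort and plot types.

    Cells are indexed row-major from the lower-left corner of the extent
    (index = row * n_cols + col, rows increasing with y).
    """

    n_cells: int
    cell_size: float
    extent: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)
    shape: tuple[int, int]  # (n_rows, n_cols)
    cell_centers: np.ndarray  # (n_cells, 2) meters
    distance: np.ndarray  # (n_cells, n_cells) kilometers
    plot_type: np.ndarray  # (n_cells,) str in PLOT_TYPES
    years: np.ndarray  # sorted study years
    effort: np.ndarray  # (n_cells, n_years) binary s[k, t]
    crs_note: str = "planar projected coordinates (meters); projection supplied by the user"

    def __post_init__(self) -> None:
        if self.effort.shape != (self.n_cells, len(self.years)):
            raise ValueError("effort must have shape (n_cells, n_years)")
        unsampled = self.plot_type == "unsampled"
        if np.any(self.effort[unsampled].sum(axis=1) > 0):
            bad = np.nonzero(unsampled & (self.effort.sum(axis=1) > 0))[0]
            raise ValueError(f"unsampled cells with nonzero effort: {bad.tolist()}")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= len(self.years) or self.years[idx] != year:
            raise ValueError(f"year {year} outside the study span {self.years[0]}-{self.years[-1]}")
        return idx

    def s(self, cell: int, year: int) -> int:
        """Effort indicator s[k, t] for one cell and calendar year."""
        return int(self.effort[cell, self.year_index(year)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x_center": self.cell_centers[:, 0],
                "y_center": self.cell_centers[:, 1],
                "plot_type": self.plot_type,
            }
        )

    def metadata(self) -> dict:
        return {
            "cell_size": self.cell_size,
            "extent": list(self.extent),
            "shape": list(self.shape),
            "n_cells": self.n_cells,
            "years": [int(y) for y in self.years],
            "crs_note": self.crs_note,
        }


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float,
    effort_table: pd.DataFrame,
) -> StudyGrid:
    """Build a :class:`StudyGrid` from a rectangular extent and effort table.

    Parameters
    ----------
    extent
        ``(xmin, ymin, xmax, ymax)`` in meters; both side lengths must be
        positive integer multiples of ``cell_size``.
    cell_size
        Cell side length in meters.
    effort_table
        Long-format table with columns ``cell_id, year, sampled, plot_type``.
        Cells absent from the table are ``unsampled`` with zero effort; rows
        referencing unknown cells are rejected.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    wx, wy = xmax - xmin, ymax - ymin
    if wx <= 0 or wy <= 0:
        raise ValueError("extent must be a non-degenerate rectangle (xmin < xmax, ymin < ymax)")
    n_cols, n_rows = wx / cell_size, wy / cell_size
    if abs(n_cols - round(n_cols)) > 1e-9 or abs(n_rows - round(n_rows)) > 1e-9:
        raise ValueError("extent dimensions must be integer multiples of cell_size")
    n_cols, n_rows = int(round(n_cols)), int(round(n_rows))
    n_cells = n_cols * n_rows

    cols = np.arange(n_cols)
    rows = np.arange(n_rows)
    cx = xmin + (cols + 0.5) * cell_size
    cy = ymin + (rows + 0.5) * cell_size
    gx, gy = np.meshgrid(cx, cy)  # row-major: index = row * n_cols + col
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    distance_km = cdist(centers, centers) / 1000.0

    required = {"cell_id", "year", "sampled", "plot_type"}
    missing = required - set(effort_table.columns)
    if missing:
        raise ValueError(f"effort table missing columns: {sorted(missing)}")
    eff = effort_table.copy()
    eff["cell_id"] = eff["cell_id"].astype(int)
    bad_cells = eff.loc[(eff["cell_id"] < 0) | (eff["cell_id"] >= n_cells), "cell_id"]
    if len(bad_cells):
        raise ValueError(f"effort rows reference unknown cells: {sorted(bad_cells.unique().tolist())}")
    bad_types = set(eff["plot_type"].unique()) - set(PLOT_TYPES)
    if bad_types:
        raise ValueError(f"unknown plot types: {sorted(bad_types)}")
    ptypes = eff.groupby("cell_id")["plot_type"].nunique()
    if (ptypes > 1).any():
        raise ValueError(
            f"cells with conflicting plot types: {ptypes[ptypes > 1].index.tolist()}"
        )

    years = np.arange(int(eff["year"].min()), int(eff["year"].max()) + 1)
    plot_type = np.full(n_cells, "unsampled", dtype=object)
    for cell, ptype in eff.groupby("cell_id")["plot_type"].first().items():
        plot_type[cell] = ptype
    effort = np.zeros((n_cells, len(years)), dtype=np.int8)
    sampled = eff[eff["sampled"].astype(int) == 1]
    if len(sampled):
        t_idx = sampled["year"].astype(int).to_numpy() - years[0]
        effort[sampled["cell_id"].to_numpy(), t_idx] = 1
    mislabelled = (plot_type == "unsampled") & (effort.sum(axis=1) > 0)
    if mislabelled.any():
        raise ValueError(
            f"cells labelled unsampled but with effort: {np.nonzero(mislabelled)[0].tolist()}"
        )

    return StudyGrid(
        n_cells=n_cells,
        cell_size=float(cell_size),
        extent=(xmin, ymin, xmax, ymax),
        shape=(n_rows, n_cols),
        cell_centers=centers,
        distance=distance_km,
        plot_type=plot_type.astype(str),
        years=years,
        effort=effort,
    )


def climate_pc(temperature: np.ndarray, precipitation: np.ndarray) -> ClimateSurface:
    """First principal component of standardized temperature and precipitation.

    Both covariates are standardized to zero mean / unit variance over cells;
    PC1 of their 2x2 correlation matrix gives one score per cell, sign-fixed
    so the temperature loading is positive (larger score = hotter and drier).
    """
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(precipitation, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("temperature and precipitation must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise ValueError("climate covariates contain non-finite values")
    sd_t, sd_p = t.std(ddof=1), p.std(ddof=1)
    if sd_t == 0 or sd_p == 0:
        raise ValueError("constant covariate: PCA undefined")
    z = np.column_stack([(t - t.mean()) / sd_t, (p - p.mean()) / sd_p])
    corr = z.T @ z / (len(t) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    score = z @ v
    return ClimateSurface(
        score=score,
        loadings=v,
        variance_explained=float(eigvals[-1] / eigvals.sum()),
    )


def snap_to_cell(point: tuple[float, float], grid: StudyGrid) -> int:
    """Index of the cell containing ``point`` (half-open square convention).

    Cell (row, col) covers ``[x, x + cell_size) x [y, y + cell_size)``; a
    point on a shared edge belongs to the increasing-coordinate side.
    """
    x, y = float(point[0]), float(point[1])
    xmin, ymin, xmax, ymax = grid.extent
    if not (xmin <= x < xmax and ymin <= y < ymax):
        raise ValueError(f"point ({x}, {y}) outside the grid extent {grid.extent}")
    col = int(np.floor((x - xmin) / grid.cell_size))
    row = int(np.floor((y - ymin) / grid.cell_size))
    return row * grid.shape[1] + col
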
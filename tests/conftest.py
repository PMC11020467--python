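import numpy as np
import pandas as pd
import pytest

from cjsdisp import (
    AgeClass,
    ClimateSurface,
    ModelParams,
    build_grid,
)


def make_effort(n_cells, years, sampled_cells=None, plot_types=None):
    """Long-format effort table; by default every cell intensive and sampled."""
    sampled_cells = range(n_cells) if sampled_cells is None else sampled_cells
    rows = []
    for cell in sampled_cells:
        ptype = plot_types.get(cell, "intensive") if plot_types else "intensive"
        for year in years:
            rows.append(
                {"cell_id": cell, "year": year, "sampled": 1, "plot_type": ptype}
            )
    return pd.DataFrame(rows)


def line_grid(n_cells, years, **kwargs):
    """1 x n_cells grid of 800 m cells with the given effort years."""
    return build_grid(
        (0.0, 0.0, 800.0 * n_cells, 800.0),
        800.0,
        make_effort(n_cells, years, **kwargs),
    )


def flat_climate(grid):
    """Zero-score climate surface (no climate effect on the kernel)."""
    return ClimateSurface(
        score=np.zeros(grid.n_cells), loadings=np.array([1.0, 0.0]), variance_explained=1.0
    )


def linear_climate(grid, slope=0.5):
    """Deterministic, zero-mean score increasing with cell index."""
    score = slope * (np.arange(grid.n_cells) - (grid.n_cells - 1) / 2)
    return ClimateSurface(
        score=score, loadings=np.array([0.7, -0.7]), variance_explained=0.9
    )


@pytest.fixture
def default_params():
    return ModelParams(
        beta1_nestling=1.0,
        beta1_adult=4.0,
        beta2_nestling=-0.41,
        beta2_adult=0.18,
        phi_nestling=0.10,
        phi_adult=0.55,
        p1=0.9,
        p2=0.5,
    )


def random_params(rng):
    """Random parameter draw with moderate values for oracle comparisons."""
    return ModelParams(
        beta1_nestling=rng.uniform(0.1, 3.0),
        beta1_adult=rng.uniform(0.1, 6.0),
        beta2_nestling=rng.normal(scale=0.8),
        beta2_adult=rng.normal(scale=0.8),
        phi_nestling=rng.uniform(0.02, 0.3),
        phi_adult=rng.uniform(0.2, 0.9),
        p1=rng.uniform(0.8, 1.0),
        p2=rng.uniform(0.1, 0.9),
    )
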
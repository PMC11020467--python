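"""Delimited-text input/output for every pipeline stage.

All formats are plain text: capture histories and effort schedules as CSV,
climate as a per-cell CSV, the grid as a cell table plus a JSON metadata
block, posterior draws as CSV with chain/iteration columns, summaries as
JSON, and kernel maps as CSV or ESRI ASCII grid rasters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import StudyGrid, build_grid
from .inference import PARAM_NAMES, Posterior, summarize
from .kernel import AgeClass, ModelParams
from .statespace import CaptureHistory

__all__ = [
    "read_captures",
    "write_captures",
    "read_effort",
    "write_effort",
    "read_climate",
    "write_climate",
    "write_grid",
    "read_grid",
    "read_params",
    "write_params",
    "write_posterior",
    "read_posterior",
    "write_summary_json",
    "write_kernel_map",
    "write_ascii_raster",
]


def read_captures(path) -> list[CaptureHistory]:
    """Read capture histories: one row per detection.

    Columns ``individual_id, year, cell_id, age_at_first`` (an optional
    ``plot_id`` column is carried by the field data but not needed here).
    Not-detected years are implicit. Duplicate same-year detections of an
    individual at the same cell collapse to one; conflicting cells within a
    year are rejected.
    """
    df = pd.read_csv(path)
    required = {"individual_id", "year", "cell_id", "age_at_first"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"capture table missing columns: {sorted(missing)}")
    histories = []
    for ind_id, rows in df.groupby("individual_id", sort=False):
        ages = set(rows["age_at_first"])
        if len(ages) > 1:
            raise ValueError(f"individual {ind_id}: inconsistent age_at_first {sorted(ages)}")
        per_year = rows.groupby("year")["cell_id"].unique()
        conflicts = per_year[per_year.apply(len) > 1]
        if len(conflicts):
            raise ValueError(
                f"individual {ind_id}: conflicting cells within year(s) "
                f"{conflicts.index.tolist()}"
            )
        detections = {int(y): int(c[0]) for y, c in per_year.items()}
        histories.append(
            CaptureHistory(
                individual_id=str(ind_id),
                first_year=min(detections),
                age_at_first=AgeClass(ages.pop()),
                detections=detections,
            )
        )
    return histories


def write_captures(histories, path) -> None:
    rows = [
        {
            "individual_id": h.individual_id,
            "year": year,
            "cell_id": cell,
            "age_at_first": h.age_at_first.value,
        }
        for h in histories
        for year, cell in sorted(h.detections.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_effort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_effort(effort_table: pd.DataFrame, path) -> None:
    effort_table.to_csv(path, index=False)


def read_climate(path) -> tuple[np.ndarray, np.ndarray]:
    """Read per-cell climate covariates ``cell_id, temperature, precipitation``."""
    df = pd.read_csv(path).sort_values("cell_id")
    if not np.array_equal(df["cell_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("climate table must cover cell ids 0..N-1 exactly once")
    return df["temperature"].to_numpy(float), df["precipitation"].to_numpy(float)


def write_climate(temperature, precipitation, path) -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(len(temperature)),
            "temperature": temperature,
            "precipitation": precipitation,
        }
    ).to_csv(path, index=False)


def write_grid(grid: StudyGrid, csv_path, meta_path) -> None:
    grid.to_frame().to_csv(csv_path, index=False)
    Path(meta_path).write_text(json.dumps(grid.metadata(), indent=2))


def read_grid(meta_path, effort_path) -> StudyGrid:
    """Rebuild a grid from its JSON metadata and the effort schedule."""
    meta = json.loads(Path(meta_path).read_text())
    return build_grid(tuple(meta["extent"]), meta["cell_size"], read_effort(effort_path))


def read_params(path) -> ModelParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    unknown = set(data) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    return ModelParams(**data)


def write_params(params: ModelParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def write_posterior(posterior: Posterior, path) -> None:
    posterior.to_dataframe().to_csv(path, index=False)


def read_posterior(path) -> Posterior:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c not in ("chain", "iteration")]
    n_chains = df["chain"].nunique()
    n_iter = df["iteration"].nunique()
    draws = (
        df.sort_values(["chain", "iteration"])[names]
        .to_numpy()
        .reshape(n_chains, n_iter, len(names))
    )
    return Posterior(draws=draws, param_names=tuple(names))


def write_summary_json(posterior: Posterior, path, extra_meta: dict | None = None) -> None:
    payload = {
        "parameters": summarize(posterior),
        "rhat": {k: float(v) for k, v in posterior.rhat.items()},
        "meta": {**posterior.meta, **(extra_meta or {})},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_kernel_map(probabilities, path) -> None:
    pd.DataFrame(
        {"cell_id": np.arange(len(probabilities)), "probability": probabilities}
    ).to_csv(path, index=False)


def write_ascii_raster(values, grid: StudyGrid, path, nodata: float = -9999.0) -> None:
    """Write per-cell values as an ESRI ASCII grid aligned to the study grid."""
    n_rows, n_cols = grid.shape
    arr = np.asarray(values, dtype=float).reshape(n_rows, n_cols)
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {grid.extent[0]}\n"
        f"yllcorner {grid.extent[1]}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in arr[::-1])
    Path(path).write_text(header + body + "\n")
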
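"""Descriptive outputs: dispersal distances, return rates, climate use.

These summaries operate on raw capture histories, independent of the fitted
model: observed dispersal records (natal = banding location to first
redetection; adult = detections in successive observed years), per-age return
rates, and the empirical climate-score distributions at dispersal
destinations versus what the landscape offers.

Distances are between snapped cell centers, in meters. Capture histories at
the grid level cannot resolve movements below the cell size; records carry an
explicit distance field so finer, raw-coordinate distances can be substituted
when territory or nest coordinates are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import gaussian_kde

from .grid import ClimateSurface, StudyGrid
from .kernel import AgeClass


__all__ = [
    "DispersalRecord",
    "ReturnRate",
    "observed_dispersal",
    "dispersal_summary",
    "return_rates",
    "climate_distributions",
]


@dataclass(frozen=True)
class DispersalRecord:
    """One observed between-year movement (or revisit) of an individual."""

    individual_id: str
    age: AgeClass  # age at the start of the move
    from_cell: int
    to_cell: int
    from_year: int
    to_year: int
    distance: float  # meters

    def __post_init__(self) -> None:
        if self.to_year <= self.from_year:
            raise ValueError("to_year must exceed from_year")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


class ReturnRate(NamedTuple):
    n_banded: int
    n_returned: int
    rate: float


def _cell_distance_m(grid: StudyGrid, a: int, b: int) -> float:
    return float(np.hypot(*(grid.cell_centers[a] - grid.cell_centers[b])))


def observed_dispersal(
    histories,
    grid: StudyGrid,
    pairing: str = "first_to_next",
) -> list[DispersalRecord]:
    """Observed dispersal records from capture histories.

    Natal records pair the banding location of a nestling with its first
    redetection (``pairing="first_to_next"``; ``"consecutive_only"`` keeps
    only returns in the year immediately after hatch). Adult records pair
    detections in successive observed years — including the later moves of
    birds banded as nestlings, which are adult moves.
    """
    if pairing not in ("first_to_next", "consecutive_only"):
        raise ValueError(f"unknown pairing rule: {pairing!r}")
    records: list[DispersalRecord] = []
    for h in histories:
        years = h.detection_years
        for y_from, y_to in zip(years, years[1:]):
            c_from, c_to = h.detections[y_from], h.detections[y_to]
            is_natal = h.age_at_first == AgeClass.NESTLING and y_from == h.first_year
            if is_natal and pairing == "consecutive_only" and y_to != y_from + 1:
                continue
            records.append(
                DispersalRecord(
                    individual_id=h.individual_id,
                    age=AgeClass.NESTLING if is_natal else AgeClass.ADULT,
                    from_cell=c_from,
                    to_cell=c_to,
                    from_year=y_from,
                    to_year=y_to,
                    distance=_cell_distance_m(grid, c_from, c_to),
                )
            )
    return records


def dispersal_summary(records) -> dict[AgeClass, dict[str, float]]:
    """Per-age median and range of observed dispersal distances (meters)."""
    out: dict[AgeClass, dict[str, float]] = {}
    for age in AgeClass:
        d = np.array([r.distance for r in records if r.age == age])
        if len(d):
            out[age] = {
                "n": int(len(d)),
                "median": float(np.median(d)),
                "min": float(d.min()),
                "max": float(d.max()),
            }
        else:
            out[age] = {"n": 0, "median": np.nan, "min": np.nan, "max": np.nan}
    return out


def return_rates(histories) -> dict[AgeClass, ReturnRate]:
    """Fraction of banded individuals redetected at least once, by age at banding.

    A raw datum, distinct from model-based apparent survival: repeated
    detections within one year count once, and row order is irrelevant.
    """
    counts = {age: [0, 0] for age in AgeClass}
    for h in histories:
        counts[h.age_at_first][0] += 1
        if h.redetected:
            counts[h.age_at_first][1] += 1
    return {
        age: ReturnRate(n, k, k / n if n else np.nan)
        for age, (n, k) in counts.items()
    }


def climate_distributions(
    records,
    climate: ClimateSurface,
    grid: StudyGrid,
    histories=None,
    include_delayed_natal: bool = False,
) -> dict[str, np.ndarray]:
    """Empirical climate-score distributions: destinations vs availability.

    Returns scores (a) at dispersal destination cells per age class, (b) over
    all grid cells ("available"), and (c) at first-banding cells (from
    ``histories`` when given, else the origins of the records). By default,
    nestlings first redetected more than one year after hatching are excluded
    from the natal destination distribution (their intermediate moves are
    unobserved); pass ``include_delayed_natal=True`` to keep them.
    """
    score = climate.score
    out: dict[str, np.ndarray] = {"available": score.copy()}
    for age in AgeClass:
        dest = [
            r.to_cell
            for r in records
            if r.age == age
            and (
                include_delayed_natal
                or age == AgeClass.ADULT
                or r.to_year == r.from_year + 1
            )
        ]
        out[f"destination_{age.value}"] = score[np.array(dest, dtype=int)] if dest else np.array([])
    if histories is not None:
        origin_cells = [h.first_cell for h in histories]
    else:
        seen: dict[str, int] = {}
        for r in sorted(records, key=lambda r: r.from_year):
            seen.setdefault(r.individual_id, r.from_cell)
        origin_cells = list(seen.values())
    out["origin"] = score[np.array(origin_cells, dtype=int)] if origin_cells else np.array([])
    return out


def kde_density(values: np.ndarray, eval_points: np.ndarray) -> np.ndarray:
    """Gaussian kernel-density summary of a score distribution."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or np.ptp(values) == 0:
        raise ValueError("kernel density needs at least two distinct values")
    return gaussian_kde(values)(np.asarray(eval_points, dtype=float))
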
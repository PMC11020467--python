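"""Age-specific anisotropic dispersal kernel and destination probabilities.

The kernel gives the relative weight of destination cell ``k`` for an
individual currently at cell ``j``:

    h[j, k] = exp(-beta1_a * X[j, k] + beta2_a * c[k])

where ``X`` is the center-to-center distance in kilometers, ``c`` the
standardized climate score, and ``a`` the age class (nestling in the hatch
year, adult thereafter). ``beta1 > 0`` controls distance decay; ``beta2 < 0``
skews the kernel away from hot/dry cells. Normalizing the weights over the
study-area cells yields the multinomial destination probabilities ``theta``,
conditional on surviving and remaining in the study area; emigration beyond
the grid is absorbed by apparent survival, not by the kernel.

Weights are evaluated on the log scale and normalized with a max shift so
that very steep kernels (large ``beta1 * X``) never underflow to all-zero
rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import logsumexp

from .grid import ClimateSurface, StudyGrid

__all__ = [
    "AgeClass",
    "ModelParams",
    "kernel_weights",
    "log_kernel_weights",
    "transition_probs",
    "log_transition_matrix",
    "predict_kernel_map",
]


class AgeClass(str, Enum):
    """Age class: an individual is a nestling only in its hatch year."""

    NESTLING = "nestling"
    ADULT = "adult"


@dataclass(frozen=True)
class ModelParams:
    """Kernel, survival and detection parameters.

    beta1_* : distance decay per kilometer, strictly positive
    beta2_* : climate effect per unit standardized climate score
    phi_*   : apparent survival (survive AND remain in the study area)
    p1, p2  : detection probability on intensive / auxiliary plots
    """

    beta1_nestling: float
    beta1_adult: float
    beta2_nestling: float
    beta2_adult: float
    phi_nestling: float
    phi_adult: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not (self.beta1_nestling > 0 and self.beta1_adult > 0):
            raise ValueError("beta1 must be strictly positive for both age classes")
        for name in ("phi_nestling", "phi_adult", "p1", "p2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("beta2_nestling", "beta2_adult"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def beta1(self, age: AgeClass) -> float:
        return self.beta1_nestling if age == AgeClass.NESTLING else self.beta1_adult

    def beta2(self, age: AgeClass) -> float:
        return self.beta2_nestling if age == AgeClass.NESTLING else self.beta2_adult

    def phi(self, age: AgeClass) -> float:
        return self.phi_nestling if age == AgeClass.NESTLING else self.phi_adult

    def to_dict(self) -> dict:
        return {
            "beta1_nestling": self.beta1_nestling,
            "beta1_adult": self.beta1_adult,
            "beta2_nestling": self.beta2_nestling,
            "beta2_adult": self.beta2_adult,
            "phi_nestling": self.phi_nestling,
            "phi_adult": self.phi_adult,
            "p1": self.p1,
            "p2": self.p2,
        }


def _check_climate(climate: ClimateSurface, grid: StudyGrid) -> None:
    if len(climate.score) != grid.n_cells:
        raise ValueError("climate score length does not match the number of grid cells")
    if not np.all(np.isfinite(climate.score)):
        raise ValueError("non-finite climate score")


def log_kernel_weights(
    origin: int,
    age: AgeClass,
    params: ModelParams,
    grid: StudyGrid,
    climate: ClimateSurface,
) -> np.ndarray:
    """Log kernel weights ``-beta1 * X[origin, :] + beta2 * c`` for one origin."""
    if not (0 <= origin < grid.n_cells):
        raise ValueError(f"origin cell {origin} outside 0..{grid.n_cells - 1}")
    _check_climate(climate, grid)
    return -params.beta1(age) * grid.distance[origin] + params.beta2(age) * climate.score


def kernel_weights(origin, age, params, grid, climate) -> np.ndarray:
    """Unnormalized kernel weights for one origin cell (linear scale)."""
    return np.exp(log_kernel_weights(origin, age, params, grid, climate))


def transition_probs(origin, age, params, grid, climate) -> np.ndarray:
    """Destination probabilities theta for one origin: normalized kernel weights."""
    lw = log_kernel_weights(origin, age, params, grid, climate)
    return np.exp(lw - logsumexp(lw))


def log_transition_matrix(
    age: AgeClass,
    params: ModelParams,
    grid: StudyGrid,
    climate: ClimateSurface,
) -> np.ndarray:
    """Log of the full N x N destination-probability matrix (rows = origins)."""
    _check_climate(climate, grid)
    lw = -params.beta1(age) * grid.distance + params.beta2(age) * climate.score[None, :]
    return lw - logsumexp(lw, axis=1, keepdims=True)


def predict_kernel_map(origin, age, posterior_or_params, grid, climate, max_draws: int = 1000) -> np.ndarray:
    """Per-cell dispersal probability surface from one origin.

    For fixed :class:`ModelParams` this is exactly :func:`transition_probs`;
    for a posterior it is the posterior mean of ``theta`` over (at most
    ``max_draws``, evenly strided) retained draws.
    """
    if isinstance(posterior_or_params, ModelParams):
        return transition_probs(origin, age, posterior_or_params, grid, climate)
    draws = list(posterior_or_params.iter_params(max_draws=max_draws))
    if not draws:
        raise ValueError("empty posterior")
    acc = np.zeros(grid.n_cells)
    for p in draws:
        acc += transition_probs(origin, age, p, grid, climate)
    return acc / len(draws)
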
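"""Latent-state model and exact marginalized likelihood.

The model is a discrete-time, discrete-space Cormack-Jolly-Seber extension.
After first capture, each individual each year (i) survives and remains in
the study area with age-specific apparent survival ``phi_a`` (death and
permanent emigration are confounded and absorbing), (ii) if alive, moves to a
grid cell drawn from the multinomial destination probabilities ``theta`` of
the dispersal kernel, and (iii) is detected at its cell with probability
``p1`` (intensive plots) or ``p2`` (auxiliary plots) when the cell was
surveyed that year, and never otherwise. Likelihoods condition on the first
capture (CJS conditioning), so birds never seen again still contribute — the
model must not condition on redetection, which would bias dispersal toward
the surveyed plots.

Rather than sampling the latent alive/location states, the likelihood sums
over them exactly with the forward algorithm on the (N+1)-state chain (N
cells plus an absorbing dead/emigrated state). :class:`MarginalLikelihood`
is an optimized evaluator that exploits the structure of capture histories:

* a detection collapses the forward distribution to a point mass, so a
  consecutive-year redetection contributes a single closed-form factor
  ``phi * theta[j, k] * p_k``;
* redetections separated by gap years are batched matrix products over the
  live states (a dead bird cannot be detected later);
* the trailing "never seen after year t" factor is shared by all individuals
  last seen in the same cell and year, and comes from one backward recursion
  ``B[t, j] = (1 - phi) + phi * sum_k theta[j, k] (1 - p_k(t+1)) B[t+1, k]``.

The result is algebraically identical to brute-force path enumeration (it is
tested against it) but costs a handful of N x N matrix products per
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logit

from .grid import StudyGrid
from .kernel import AgeClass, ModelParams, log_transition_matrix

__all__ = [
    "NOT_DETECTED",
    "DEAD",
    "CaptureHistory",
    "LatentState",
    "age_schedule",
    "build_transition_matrix",
    "emission_prob",
    "detection_prob_matrix",
    "MarginalLikelihood",
    "marginal_loglik",
    "log_prior",
    "PRIOR_LOGIT_SD_P2",
]

NOT_DETECTED = None  # observation sentinel: no detection that year
DEAD = -1  # latent-state sentinel: dead or permanently emigrated

# SD of the logit-scale normal prior on p2; approximately uniform on (0, 1).
PRIOR_LOGIT_SD_P2 = 1.78


@dataclass(frozen=True)
class CaptureHistory:
    """Detections of one individual from first capture to study end.

    ``detections`` maps year -> cell for every year the individual was
    detected (including ``first_year``); years absent from the map are
    not-detected years. ``age_at_first`` is the age class at first capture.
    """

    individual_id: str
    first_year: int
    age_at_first: AgeClass
    detections: dict[int, int]

    def __post_init__(self) -> None:
        if self.first_year not in self.detections:
            raise ValueError(
                f"individual {self.individual_id}: no detection recorded at first_year"
            )
        if min(self.detections) != self.first_year:
            raise ValueError(
                f"individual {self.individual_id}: detection before first_year"
            )

    @property
    def first_cell(self) -> int:
        return self.detections[self.first_year]

    @property
    def detection_years(self) -> list[int]:
        return sorted(self.detections)

    @property
    def redetected(self) -> bool:
        return len(self.detections) > 1

    def observed_cell(self, year: int):
        """Cell of detection in ``year``, or :data:`NOT_DETECTED`."""
        return self.detections.get(year, NOT_DETECTED)


@dataclass(frozen=True)
class LatentState:
    """Simulated truth for one individual: alive flags and occupied cells."""

    alive: np.ndarray  # binary per year from first_year
    location: np.ndarray  # cell per year while alive (DEAD afterwards)

    def __post_init__(self) -> None:
        a = np.asarray(self.alive)
        if np.any(np.diff(a) > 0):
            raise ValueError("alive indicator must be non-increasing (absorbing death)")


def age_schedule(history: CaptureHistory, year: int) -> AgeClass:
    """Age class of the individual in ``year``.

    Nestling only in the hatch (first-capture) year; adult in every later
    year, including unobserved gap years. The transition out of year t is
    governed by the age in year t, so a nestling's single nestling-kernel
    transition is hatch year -> hatch year + 1.
    """
    if year < history.first_year:
        raise ValueError(
            f"year {year} precedes first capture ({history.first_year}) "
            f"of individual {history.individual_id}"
        )
    if history.age_at_first == AgeClass.NESTLING and year == history.first_year:
        return AgeClass.NESTLING
    return AgeClass.ADULT


def build_transition_matrix(age, params, grid, climate) -> np.ndarray:
    """(N+1) x (N+1) yearly transition matrix over live cells plus dead state.

    Entry (j, k) for live j, k is ``phi_a * theta[j, k]``; column N receives
    the death/emigration mass ``1 - phi_a``; the dead row is absorbing.
    """
    n = grid.n_cells
    phi = params.phi(age)
    theta = np.exp(log_transition_matrix(age, params, grid, climate))
    m = np.zeros((n + 1, n + 1))
    m[:n, :n] = phi * theta
    m[:n, n] = 1.0 - phi
    m[n, n] = 1.0
    return m


def detection_prob_matrix(params: ModelParams, grid: StudyGrid) -> np.ndarray:
    """(n_years, n_cells) matrix of detection probabilities p_k(t).

    ``p1 * s[k, t]`` on intensive plots, ``p2 * s[k, t]`` on auxiliary plots,
    zero on unsampled cells.
    """
    p_cell = np.where(
        grid.plot_type == "intensive", params.p1,
        np.where(grid.plot_type == "auxiliary", params.p2, 0.0),
    )
    return grid.effort.T * p_cell[None, :]


def emission_prob(state, observation, year, params, grid) -> float:
    """P(observation | latent state) for one individual-year.

    ``state`` is a live cell index or :data:`DEAD`; ``observation`` a cell
    index or :data:`NOT_DETECTED`. A dead/emigrated individual is never
    detected; a live one is detected at its own cell with the plot-type
    detection probability times the effort indicator, and nowhere else.
    """
    if observation is not NOT_DETECTED:
        observation = int(observation)
        if not (0 <= observation < grid.n_cells):
            raise ValueError(f"observation cell {observation} outside the grid")
        if grid.s(observation, year) == 0:
            raise ValueError(
                f"observation at cell {observation} in year {year}, "
                "but the cell was not sampled (s = 0)"
            )
    if state == DEAD:
        return 1.0 if observation is NOT_DETECTED else 0.0
    state = int(state)
    ptype = grid.plot_type[state]
    p_base = params.p1 if ptype == "intensive" else params.p2 if ptype == "auxiliary" else 0.0
    p_det = p_base * grid.s(state, year)
    if observation is NOT_DETECTED:
        return 1.0 - p_det
    return p_det if observation == state else 0.0


@dataclass
class _GapSegment:
    origins: list[int] = field(default_factory=list)
    dests: list[int] = field(default_factory=list)


class MarginalLikelihood:
    """Reusable exact marginal log-likelihood evaluator for fixed data.

    Construction validates and indexes the capture histories against the grid
    (a one-off cost); each call with a new :class:`ModelParams` then costs a
    few N x N matrix operations. Use :func:`marginal_loglik` for one-off
    evaluations.
    """

    def __init__(self, histories, grid: StudyGrid, climate) -> None:
        self.grid = grid
        self.climate = climate
        self.n_individuals = len(list(histories))
        if self.n_individuals == 0:
            raise ValueError("no capture histories supplied")
        n, years = grid.n_cells, grid.years
        T = len(years)
        self._T = T

        # masks reused when building the detection matrix
        self._intensive = (grid.plot_type == "intensive").astype(float)
        self._auxiliary = (grid.plot_type == "auxiliary").astype(float)

        # consecutive-detection steps, per age of the step
        cons = {AgeClass.NESTLING: ([], [], []), AgeClass.ADULT: ([], [], [])}
        # gap segments grouped by (t_from, t_to, nestling_first_step)
        self._gaps: dict[tuple[int, int, bool], _GapSegment] = {}
        # tails: counts of individuals last seen at (t, k), by age at last sighting
        tail_n = np.zeros((T, n))
        tail_a = np.zeros((T, n))

        for h in histories:
            self._validate(h)
            t_idx = [grid.year_index(y) for y in h.detection_years]
            cells = [h.detections[y] for y in h.detection_years]
            nestling = h.age_at_first == AgeClass.NESTLING
            t0 = grid.year_index(h.first_year)
            for (ta, ja), (tb, jb) in zip(zip(t_idx, cells), zip(t_idx[1:], cells[1:])):
                step_age = (
                    AgeClass.NESTLING if (nestling and ta == t0) else AgeClass.ADULT
                )
                if tb == ta + 1:
                    js, ks, ts = cons[step_age]
                    js.append(ja)
                    ks.append(jb)
                    ts.append(tb)
                else:
                    key = (ta, tb, step_age == AgeClass.NESTLING)
                    seg = self._gaps.setdefault(key, _GapSegment())
                    seg.origins.append(ja)
                    seg.dests.append(jb)
            t_last, k_last = t_idx[-1], cells[-1]
            if nestling and t_last == t0:
                tail_n[t_last, k_last] += 1
            else:
                tail_a[t_last, k_last] += 1

        self._cons = {
            age: tuple(np.asarray(a, dtype=int) for a in arrays)
            for age, arrays in cons.items()
        }
        self._tail_n = tail_n
        self._tail_a = tail_a
        self._tail_n_idx = np.nonzero(tail_n)
        self._tail_a_idx = np.nonzero(tail_a)

    def _validate(self, h: CaptureHistory) -> None:
        grid = self.grid
        for year, cell in h.detections.items():
            if not (0 <= cell < grid.n_cells):
                raise ValueError(
                    f"individual {h.individual_id}: detection at unknown cell {cell}"
                )
            try:
                sampled = grid.s(cell, year)
            except ValueError as err:
                raise ValueError(f"individual {h.individual_id}: {err}") from err
            if sampled == 0:
                raise ValueError(
                    f"individual {h.individual_id}: detection in year {year} at "
                    f"cell {cell}, which was not sampled that year"
                )
            if grid.plot_type[cell] == "unsampled":
                raise ValueError(
                    f"individual {h.individual_id}: detection at unsampled-plot cell {cell}"
                )

    def __call__(self, params: ModelParams) -> float:
        grid, T = self.grid, self._T
        log_theta_n = log_transition_matrix(AgeClass.NESTLING, params, grid, self.climate)
        log_theta_a = log_transition_matrix(AgeClass.ADULT, params, grid, self.climate)
        theta_n, theta_a = np.exp(log_theta_n), np.exp(log_theta_a)
        phi = {AgeClass.NESTLING: params.phi_nestling, AgeClass.ADULT: params.phi_adult}

        p_cell = params.p1 * self._intensive + params.p2 * self._auxiliary
        P = grid.effort.T * p_cell[None, :]  # (T, N)
        q = 1.0 - P

        # backward "no detection in any later year" tables
        B = np.ones((T, grid.n_cells))
        for t in range(T - 2, -1, -1):
            B[t] = (1.0 - phi[AgeClass.ADULT]) + phi[AgeClass.ADULT] * (
                theta_a @ (q[t + 1] * B[t + 1])
            )
        Bn = np.ones((T, grid.n_cells))
        if T > 1:
            m = (q[1:] * B[1:]).T  # (N, T-1)
            Bn[: T - 1] = (
                (1.0 - phi[AgeClass.NESTLING])
                + phi[AgeClass.NESTLING] * (theta_n @ m)
            ).T

        ll = 0.0
        with np.errstate(divide="ignore"):
            log_theta = {AgeClass.NESTLING: log_theta_n, AgeClass.ADULT: log_theta_a}
            for age, (js, ks, ts) in self._cons.items():
                if len(js) == 0:
                    continue
                pdet = P[ts, ks]
                if np.any(pdet <= 0.0) or phi[age] <= 0.0:
                    return -np.inf
                ll += len(js) * np.log(phi[age])
                ll += float(np.sum(log_theta[age][js, ks]) + np.sum(np.log(pdet)))

            for (ta, tb, nestling_first), seg in self._gaps.items():
                first_age = AgeClass.NESTLING if nestling_first else AgeClass.ADULT
                theta_first = theta_n if nestling_first else theta_a
                origins = np.asarray(seg.origins)
                dests = np.asarray(seg.dests)
                v = phi[first_age] * theta_first[origins]  # arrive year ta+1
                for u in range(ta + 1, tb):
                    v = phi[AgeClass.ADULT] * ((v * q[u]) @ theta_a)
                prob = v[np.arange(len(dests)), dests] * P[tb, dests]
                if np.any(prob <= 0.0):
                    return -np.inf
                ll += float(np.sum(np.log(prob)))

            for tails, table in ((self._tail_a_idx, B), (self._tail_n_idx, Bn)):
                ts, ks = tails
                if len(ts) == 0:
                    continue
                vals = table[ts, ks]
                if np.any(vals <= 0.0):
                    return -np.inf
                counts = (self._tail_a if table is B else self._tail_n)[ts, ks]
                ll += float(np.sum(counts * np.log(vals)))
        return ll


def marginal_loglik(histories, params, grid, climate) -> float:
    """Exact marginal log-likelihood of the capture histories.

    Sums, over individuals, the log-probability of the observations after
    first capture given the first-capture cell and ``params``, marginalizing
    the latent alive/location process with the forward algorithm.
    """
    return MarginalLikelihood(histories, grid, climate)(params)


def log_prior(params: ModelParams) -> float:
    """Log prior density of the model parameters (-inf outside support).

    p1 ~ Uniform(0.8, 1); p2 ~ LogitNormal(0, 1.78) (sd on the logit scale,
    approximately uniform on probability); beta1_a ~ Exponential(rate 0.1)
    — which puts < 0.05 prior mass on mean dispersal distances 1/beta1
    beyond 30 km; beta2_a ~ Normal(0, 1); phi_nestling ~ Uniform(0, 0.3);
    phi_adult ~ Beta(5, 2).
    """
    lp = stats.uniform.logpdf(params.p1, loc=0.8, scale=0.2)
    if not (0.0 < params.p2 < 1.0):
        return -np.inf
    z = logit(params.p2)
    lp += stats.norm.logpdf(z, scale=PRIOR_LOGIT_SD_P2) - np.log(params.p2 * (1.0 - params.p2))
    lp += stats.expon.logpdf(params.beta1_nestling, scale=10.0)
    lp += stats.expon.logpdf(params.beta1_adult, scale=10.0)
    lp += stats.norm.logpdf(params.beta2_nestling)
    lp += stats.norm.logpdf(params.beta2_adult)
    lp += stats.uniform.logpdf(params.phi_nestling, loc=0.0, scale=0.3)
    lp += stats.beta.logpdf(params.phi_adult, 5.0, 2.0)
    return float(lp) if np.isfinite(lp) else -np.inf
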
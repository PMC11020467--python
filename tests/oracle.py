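"""Brute-force latent-path enumeration oracle for the marginal likelihood.

Deliberately independent of the package's likelihood code: destination
probabilities, survival and detection are recomputed here with plain scalar
arithmetic, and the likelihood of a capture history is the explicit sum over
every latent (location, alive) path. Feasible only for a handful of cells
and years.
"""

import itertools
import math

from cjsdisp import AgeClass

DEAD = "dead"


def theta_row(origin, beta1, beta2, grid, climate):
    weights = [
        math.exp(-beta1 * grid.distance[origin, k] + beta2 * climate.score[k])
        for k in range(grid.n_cells)
    ]
    total = sum(weights)
    return [w / total for w in weights]


def detection_prob(cell, year, params, grid):
    if grid.plot_type[cell] == "intensive":
        base = params.p1
    elif grid.plot_type[cell] == "auxiliary":
        base = params.p2
    else:
        base = 0.0
    return base * grid.s(cell, year)


def history_likelihood(history, params, grid, climate):
    """P(observations after first capture | first cell, params) by enumeration."""
    years = [int(y) for y in grid.years]
    start = years.index(history.first_year)
    later_years = years[start + 1 :]
    states = list(range(grid.n_cells)) + [DEAD]
    total = 0.0
    for path in itertools.product(states, repeat=len(later_years)):
        prob = 1.0
        prev = history.detections[history.first_year]
        for step, (year, state) in enumerate(zip(later_years, path)):
            age_prev = (
                AgeClass.NESTLING
                if (history.age_at_first == AgeClass.NESTLING and step == 0)
                else AgeClass.ADULT
            )
            beta1 = params.beta1(age_prev)
            beta2 = params.beta2(age_prev)
            phi = params.phi(age_prev)
            # transition
            if prev == DEAD:
                prob *= 1.0 if state == DEAD else 0.0
            elif state == DEAD:
                prob *= 1.0 - phi
            else:
                prob *= phi * theta_row(prev, beta1, beta2, grid, climate)[state]
            if prob == 0.0:
                break
            # emission
            obs = history.detections.get(year)
            if state == DEAD:
                prob *= 1.0 if obs is None else 0.0
            else:
                p_det = detection_prob(state, year, params, grid)
                if obs is None:
                    prob *= 1.0 - p_det
                else:
                    prob *= p_det if obs == state else 0.0
            if prob == 0.0:
                break
            prev = state
        total += prob
    return total


def total_loglik(histories, params, grid, climate):
    return sum(
        math.log(history_likelihood(h, params, grid, climate)) for h in histories
    )
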
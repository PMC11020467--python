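import numpy as np
import pytest
from scipy import stats

from cjsdisp import (
    AgeClass,
    CaptureHistory,
    ClimateSurface,
    MarginalLikelihood,
    ModelParams,
    NOT_DETECTED,
    age_schedule,
    build_transition_matrix,
    emission_prob,
    log_prior,
    marginal_loglik,
)
from cjsdisp.statespace import DEAD
from conftest import flat_climate, line_grid, linear_climate, make_effort, random_params
import oracle


def params_with(**kwargs):
    base = dict(
        beta1_nestling=1.0,
        beta1_adult=1.0,
        beta2_nestling=0.0,
        beta2_adult=0.0,
        phi_nestling=0.1,
        phi_adult=0.5,
        p1=0.9,
        p2=0.5,
    )
    base.update(kwargs)
    return ModelParams(**base)


class TestTransitionMatrix:
    def test_zero_survival_sends_everything_to_dead(self):
        grid = line_grid(3, [2002, 2003])
        m = build_transition_matrix(
            AgeClass.ADULT, params_with(phi_adult=0.0), grid, flat_climate(grid)
        )
        assert np.allclose(m[:3, 3], 1.0)
        assert np.allclose(m[:3, :3], 0.0)

    def test_degenerate_kernel_is_identity_on_live_cells(self):
        grid = line_grid(3, [2002, 2003])
        m = build_transition_matrix(
            AgeClass.ADULT,
            params_with(phi_adult=1.0, beta1_adult=500.0),
            grid,
            flat_climate(grid),
        )
        assert np.allclose(m[:3, :3], np.eye(3), atol=1e-12)

    def test_two_cell_numeric_row(self):
        grid = line_grid(2, [2002, 2003])
        climate = ClimateSurface(np.array([0.0, 1.0]), np.array([1.0, 0.0]), 1.0)
        p = params_with(beta1_adult=1.0, beta2_adult=-0.41, phi_adult=0.5)
        m = build_transition_matrix(AgeClass.ADULT, p, grid, climate)
        assert m[0] == pytest.approx([0.38515, 0.11485, 0.5], abs=1e-4)

    def test_rows_sum_to_one_and_dead_absorbing(self):
        grid = line_grid(4, [2002, 2003])
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = build_transition_matrix(
                AgeClass.NESTLING, random_params(rng), grid, linear_climate(grid)
            )
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert m[4, 4] == 1.0


class TestEmission:
    def test_alive_intensive_cell(self):
        grid = line_grid(2, [2002])
        p = params_with(p1=0.9)
        assert emission_prob(0, 0, 2002, p, grid) == pytest.approx(0.9)
        assert emission_prob(0, NOT_DETECTED, 2002, p, grid) == pytest.approx(0.1)

    def test_alive_elsewhere_cannot_be_detected_at_other_cell(self):
        grid = line_grid(2, [2002])
        assert emission_prob(1, 0, 2002, params_with(), grid) == 0.0

    def test_alive_unsampled_cell_never_detected(self):
        grid = line_grid(3, [2002], sampled_cells=[0, 1])
        assert emission_prob(2, NOT_DETECTED, 2002, params_with(), grid) == 1.0

    def test_dead_emits_nothing(self):
        grid = line_grid(2, [2002])
        assert emission_prob(DEAD, NOT_DETECTED, 2002, params_with(), grid) == 1.0
        assert emission_prob(DEAD, 0, 2002, params_with(), grid) == 0.0

    def test_observation_where_no_effort_rejected(self):
        grid = line_grid(3, [2002], sampled_cells=[0, 1])
        with pytest.raises(ValueError, match="not sampled"):
            emission_prob(2, 2, 2002, params_with(), grid)


class TestAgeSchedule:
    def test_nestling_only_in_hatch_year(self):
        h = CaptureHistory("b1", 2005, AgeClass.NESTLING, {2005: 0})
        assert age_schedule(h, 2005) == AgeClass.NESTLING
        assert age_schedule(h, 2006) == AgeClass.ADULT
        assert age_schedule(h, 2007) == AgeClass.ADULT  # even if unobserved in 2006

    def test_adult_banded_always_adult(self):
        h = CaptureHistory("a1", 2010, AgeClass.ADULT, {2010: 0})
        for year in (2010, 2011, 2015):
            assert age_schedule(h, year) == AgeClass.ADULT

    def test_year_before_first_capture_rejected(self):
        h = CaptureHistory("b2", 2005, AgeClass.NESTLING, {2005: 0})
        with pytest.raises(ValueError, match="precedes"):
            age_schedule(h, 2004)


class TestMarginalLoglik:
    def test_perfect_detection_forces_death_interpretation(self):
        # one adult seen at first capture only; p=1 everywhere, 2-year study
        grid = line_grid(3, [2002, 2003])
        h = CaptureHistory("a1", 2002, AgeClass.ADULT, {2002: 1})
        p = params_with(p1=1.0, phi_adult=0.37)
        ll = marginal_loglik([h], p, grid, flat_climate(grid))
        assert ll == pytest.approx(np.log(1 - 0.37), abs=1e-12)

    def test_no_post_capture_effort_carries_no_information(self):
        rows = make_effort(3, [2002])
        rows = rows.assign(sampled=rows["year"].eq(2002).astype(int))
        extra = make_effort(3, [2003, 2004]).assign(sampled=0)
        import pandas as pd
        from cjsdisp import build_grid

        grid = build_grid((0, 0, 2400, 800), 800, pd.concat([rows, extra]))
        h = CaptureHistory("a1", 2002, AgeClass.ADULT, {2002: 1})
        for seed in range(5):
            p = random_params(np.random.default_rng(seed))
            assert marginal_loglik([h], p, grid, flat_climate(grid)) == pytest.approx(0.0, abs=1e-14)

    def test_matches_enumeration_with_gap_year(self):
        grid = line_grid(3, [2002, 2003, 2004])
        climate = linear_climate(grid)
        h = CaptureHistory("b1", 2002, AgeClass.NESTLING, {2002: 0, 2004: 2})
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = random_params(rng)
            fast = marginal_loglik([h], p, grid, climate)
            slow = oracle.total_loglik([h], p, grid, climate)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_factorizes_over_individuals(self):
        grid = line_grid(3, [2002, 2003, 2004])
        climate = linear_climate(grid)
        hs = [
            CaptureHistory("a", 2002, AgeClass.ADULT, {2002: 0, 2003: 1}),
            CaptureHistory("b", 2002, AgeClass.NESTLING, {2002: 2}),
            CaptureHistory("c", 2003, AgeClass.ADULT, {2003: 1, 2004: 1}),
        ]
        p = params_with()
        total = marginal_loglik(hs, p, grid, climate)
        permuted = marginal_loglik(hs[::-1], p, grid, climate)
        parts = sum(marginal_loglik([h], p, grid, climate) for h in hs)
        assert total == pytest.approx(permuted, abs=1e-12)
        assert total == pytest.approx(parts, abs=1e-10)

    def test_never_redetected_likelihood_strictly_between_zero_and_one(self):
        # the model must not condition on redetection
        grid = line_grid(4, [2002, 2003, 2004])
        climate = linear_climate(grid)
        h = CaptureHistory("a1", 2002, AgeClass.ADULT, {2002: 0})
        rng = np.random.default_rng(9)
        for _ in range(10):
            p = random_params(rng)
            ll = marginal_loglik([h], p, grid, climate)
            assert -np.inf < ll < 0.0

    def test_detection_at_unsampled_year_rejected_with_id(self):
        import pandas as pd
        from cjsdisp import build_grid

        rows = pd.concat(
            [
                make_effort(2, [2002]),
                make_effort(2, [2003]).assign(sampled=0),
            ]
        )
        grid = build_grid((0, 0, 1600, 800), 800, rows)
        h = CaptureHistory("bad_bird", 2002, AgeClass.ADULT, {2002: 0, 2003: 1})
        with pytest.raises(ValueError, match="bad_bird"):
            marginal_loglik([h], params_with(), grid, flat_climate(grid))


class TestLogPrior:
    def test_p1_outside_support(self):
        assert log_prior(params_with(p1=0.75)) == -np.inf

    def test_matches_hand_built_density_sum(self):
        from scipy.special import logit

        p = params_with(
            beta1_nestling=2.0,
            beta1_adult=5.0,
            beta2_nestling=-0.4,
            beta2_adult=0.2,
            phi_nestling=0.15,
            phi_adult=0.7,
            p1=0.9,
            p2=0.4,
        )
        expected = (
            np.log(1 / 0.3)  # phi_nestling = 0.15 under Uniform(0, 0.3)
            + stats.beta.logpdf(0.7, 5, 2)
            + stats.uniform.logpdf(0.9, 0.8, 0.2)
            + stats.norm.logpdf(logit(0.4), scale=1.78)
            - np.log(0.4 * 0.6)
            + stats.expon.logpdf(2.0, scale=10.0)
            + stats.expon.logpdf(5.0, scale=10.0)
            + stats.norm.logpdf(-0.4)
            + stats.norm.logpdf(0.2)
        )
        assert log_prior(p) == pytest.approx(expected, abs=1e-12)
        # uniform prior: same contribution anywhere inside its support
        assert log_prior(params_with(phi_nestling=0.15)) == pytest.approx(
            log_prior(params_with(phi_nestling=0.25)), abs=1e-12
        )

    def test_phi_nestling_above_030_excluded(self):
        assert log_prior(params_with(phi_nestling=0.35)) == -np.inf

    def test_exponential_prior_tail_bound_on_mean_distance(self):
        # P(1/beta1 > 30 km) = P(beta1 < 1/30) under Exponential(rate 0.1)
        tail = stats.expon.cdf(1.0 / 30.0, scale=10.0)
        assert tail == pytest.approx(1 - np.exp(-0.1 / 30.0), abs=1e-12)
        assert tail == pytest.approx(0.00333, abs=1e-5)
        assert tail < 0.05

    def test_density_changes_with_beta2_as_standard_normal(self):
        d = log_prior(params_with(beta2_nestling=1.0)) - log_prior(
            params_with(beta2_nestling=0.0)
        )
        assert d == pytest.approx(-0.5, abs=1e-12)


class TestOracleEquivalence:
    """Forward-algorithm likelihood equals exhaustive latent-path enumeration."""

    @pytest.mark.parametrize(
        "n_cells,years,detections,age",
        [
            (3, [2000, 2001, 2002, 2003], {2000: 0}, AgeClass.NESTLING),
            (3, [2000, 2001, 2002, 2003], {2000: 0, 2003: 2}, AgeClass.NESTLING),
            (4, [2000, 2001, 2002], {2000: 1, 2001: 1, 2002: 3}, AgeClass.ADULT),
            (5, [2000, 2001, 2002], {2001: 4}, AgeClass.ADULT),
            (2, [2000, 2001, 2002, 2003], {2000: 0, 2001: 1, 2003: 0}, AgeClass.NESTLING),
        ],
    )
    def test_random_params_match(self, n_cells, years, detections, age):
        grid = line_grid(
            n_cells,
            years,
            plot_types={k: ("auxiliary" if k % 2 else "intensive") for k in range(n_cells)},
        )
        climate = linear_climate(grid, slope=0.4)
        first_year = min(detections)
        h = CaptureHistory("x", first_year, age, detections)
        rng = np.random.default_rng(n_cells * 100 + len(years))
        for _ in range(8):
            p = random_params(rng)
            fast = marginal_loglik([h], p, grid, climate)
            slow = oracle.total_loglik([h], p, grid, climate)
            assert fast == pytest.approx(slow, abs=1e-10)
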
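"""Theta estimation: likelihoods, the Newton scorer, corrections, batching."""

import numpy as np
import pytest
from scipy.special import expit

from effortirt import (
    EffortProfile,
    GuessingConfig,
    ItemParameters,
    NonIdentifiableError,
    PriorSpec,
    ThetaEstimate,
    bme_theta,
    corrected_theta,
    items_from_arrays,
    log_likelihood,
    mle_theta,
    sample_log_likelihood,
    score_sample,
)
from conftest import grid_argmax

LOGIT_QUARTER = float(np.log(1 / 3))  # logit(1/4) = -1.0986...


class TestLogLikelihood:
    def test_all_missing_is_empty_sum(self, demo_items):
        assert log_likelihood(0.7, [np.nan] * 7, demo_items) == 0.0

    def test_single_item(self):
        items = [ItemParameters(a=1.0, b=0.0)]
        assert log_likelihood(0.0, [1], items) == pytest.approx(np.log(0.5))

    def test_matches_brute_force_summation(self, demo_items, worked_vector):
        # independent oracle: per-item logistic evaluation summed by hand
        theta = 0.0
        expected = 0.0
        for y, item in zip(worked_vector, demo_items):
            p = 1 / (1 + np.exp(-item.a * (theta - item.b)))
            expected += y * np.log(p) + (1 - y) * np.log(1 - p)
        assert log_likelihood(theta, worked_vector,
                              demo_items) == pytest.approx(expected)

    def test_conformability_checked(self, demo_items):
        with pytest.raises(ValueError):
            log_likelihood(0.0, [1, 0], demo_items)


class TestMLE:
    def test_worked_vector_matches_grid_oracle(self, demo_items,
                                               worked_vector):
        est = mle_theta(worked_vector, demo_items)
        # frozen pre-build grid-search oracle values (step 1e-4)
        assert est.theta == pytest.approx(1.1972, abs=1e-3)
        assert est.se == pytest.approx(0.9449, abs=1e-3)
        assert est.converged and not est.at_boundary

    def test_zero_variance_vectors_hit_baker_kim_bounds(self, demo_items):
        hi = mle_theta([1] * 7, demo_items)
        lo = mle_theta([0] * 7, demo_items)
        assert hi.theta == pytest.approx(np.log(14.0))
        assert lo.theta == pytest.approx(-np.log(14.0))
        assert hi.at_boundary and lo.at_boundary
        assert hi.se > 0 and lo.se > 0

    def test_missing_items_are_dropped(self, demo_items):
        full = mle_theta([1, 1, 0, 1, np.nan, np.nan, np.nan], demo_items)
        sub = mle_theta([1, 1, 0, 1], demo_items[:4])
        assert full.theta == pytest.approx(sub.theta, abs=1e-9)
        assert full.se == pytest.approx(sub.se, abs=1e-9)

    def test_all_missing_rejected(self, demo_items):
        with pytest.raises(ValueError):
            mle_theta([np.nan] * 7, demo_items)

    def test_score_equation_holds_at_optimum(self, demo_items,
                                             worked_vector):
        est = mle_theta(worked_vector, demo_items)
        h = 1e-5
        deriv = (log_likelihood(est.theta + h, worked_vector, demo_items)
                 - log_likelihood(est.theta - h, worked_vector,
                                  demo_items)) / (2 * h)
        assert abs(deriv) < 1e-5

    def test_flat_em_likelihood_reports_nonidentifiability(self, demo_items):
        cfg = GuessingConfig(n_options=4)
        with pytest.raises(NonIdentifiableError):
            mle_theta([1, 0, 1, 0, 1, 0, 1], demo_items, model="em2pl",
                      sb_row=[0] * 7, cfg=cfg)

    def test_3pl_estimate_matches_grid_oracle(self, worked_vector):
        items = items_from_arrays(
            np.full(7, 1.3), np.linspace(-2, 2, 7),
            gamma=np.full(7, np.log(1 / 3)))
        est = mle_theta(worked_vector, items, model="3pl")

        def objective(grid):
            total = np.zeros_like(grid)
            for y, it in zip(worked_vector, items):
                p2 = expit(it.a * (grid - it.b))
                p = 0.25 + 0.75 * p2
                total += y * np.log(p) + (1 - y) * np.log(1 - p)
            return total

        assert est.theta == pytest.approx(grid_argmax(objective), abs=1e-3)


class TestBME:
    def test_worked_vector_matches_grid_oracle(self, demo_items,
                                               worked_vector):
        est = bme_theta(worked_vector, demo_items, prior=PriorSpec(0.0, 1.0))
        # frozen pre-build grid-search oracle of the log-posterior
        assert est.theta == pytest.approx(0.6517, abs=1e-3)
        assert est.se == pytest.approx(0.6653, abs=1e-3)

    def test_no_information_returns_the_prior(self, demo_items):
        est = bme_theta([np.nan] * 7, demo_items,
                        prior=PriorSpec(0.3, 0.8))
        assert est.theta == 0.3 and est.se == 0.8

    def test_zero_variance_vectors_are_estimable(self, demo_items):
        est = bme_theta([1] * 7, demo_items)
        assert np.isfinite(est.theta) and est.theta < np.log(14.0)
        assert est.converged

    def test_nonzero_prior_mean_shifts_the_mode(self, demo_items,
                                                worked_vector):
        lo = bme_theta(worked_vector, demo_items, prior=PriorSpec(-1.0, 1.0))
        hi = bme_theta(worked_vector, demo_items, prior=PriorSpec(1.0, 1.0))
        assert lo.theta < hi.theta


class TestCorrectedTheta:
    def _estimate(self, theta):
        return ThetaEstimate(theta=theta, se=0.9, method="MLE")

    def test_random_guessing_four_options(self):
        cfg = GuessingConfig(n_options=4, correction="random_guessing")
        out = corrected_theta(self._estimate(1.015), rbe=0, cfg=cfg)
        assert out.theta == pytest.approx(-1.0986, abs=1e-4)
        assert round(out.theta, 3) == -1.099
        assert np.isnan(out.se) and not out.at_boundary

    def test_random_guessing_two_options_is_zero(self):
        cfg = GuessingConfig(n_options=2, correction="random_guessing")
        assert corrected_theta(self._estimate(2.0), 0, cfg).theta == 0.0

    def test_ability_based_shifts_by_k_theta(self):
        cfg = GuessingConfig(n_options=4, correction="ability_based", k=0.228)
        out = corrected_theta(self._estimate(1.015), rbe=0, cfg=cfg)
        assert out.theta == pytest.approx(LOGIT_QUARTER + 0.228 * 1.015,
                                          abs=1e-9)
        assert out.theta == pytest.approx(-0.867, abs=5e-4)

    def test_effortful_person_passes_through(self):
        cfg = GuessingConfig(n_options=4, correction="random_guessing")
        est = self._estimate(0.5)
        assert corrected_theta(est, rbe=1, cfg=cfg) is est

    def test_requires_a_correction_rule(self):
        with pytest.raises(ValueError):
            corrected_theta(self._estimate(0.5), 0,
                            GuessingConfig(n_options=4))

    def test_too_few_options_rejected(self):
        with pytest.raises(ValueError):
            GuessingConfig(n_options=1, correction="random_guessing")


class TestScoreSample:
    def test_single_row_equals_single_person_call(self, demo_items,
                                                  worked_vector):
        batch = score_sample(worked_vector.reshape(1, -1), demo_items)
        single = mle_theta(worked_vector, demo_items)
        assert batch[0].theta == single.theta
        assert batch[0].se == single.se

    def test_all_effortful_profile_is_a_noop(self, demo_items):
        rng = np.random.default_rng(11)
        grid = rng.integers(0, 2, size=(12, 7)).astype(float)
        n = grid.shape[0]
        effort = EffortProfile(sb=np.ones((n, 7), int), rte=np.ones(n),
                               rbe=np.ones(n, int))
        cfg = GuessingConfig(n_options=4, correction="random_guessing")
        with_effort = score_sample(grid, demo_items, effort=effort, cfg=cfg)
        without = score_sample(grid, demo_items)
        for x, y in zip(with_effort, without):
            assert x.theta == y.theta

    def test_rapid_persons_receive_corrected_theta(self, demo_items):
        grid = np.array([[1, 1, 0, 1, 1, 1, 0],
                         [1, 1, 0, 1, 1, 1, 0]], dtype=float)
        effort = EffortProfile(sb=np.ones((2, 7), int),
                               rte=np.array([1.0, 0.0]),
                               rbe=np.array([1, 0]))
        cfg = GuessingConfig(n_options=4, correction="random_guessing")
        out = score_sample(grid, demo_items, effort=effort, cfg=cfg)
        assert out[0].corrected == "none"
        assert out[1].theta == pytest.approx(LOGIT_QUARTER, abs=1e-9)

    def test_row_failures_do_not_abort_the_batch(self, demo_items):
        grid = np.array([[1, 1, 0, 1, 1, 1, 0],
                         [np.nan] * 7], dtype=float)
        out = score_sample(grid, demo_items)
        assert out[0] is not None and out[1] is None


class TestSampleLogLikelihood:
    def test_em2pl_with_all_solution_behavior_equals_2pl(self, demo_items):
        rng = np.random.default_rng(5)
        grid = rng.integers(0, 2, size=(10, 7)).astype(float)
        n = grid.shape[0]
        effort = EffortProfile(sb=np.ones((n, 7), int), rte=np.ones(n),
                               rbe=np.ones(n, int))
        cfg = GuessingConfig(n_options=4)
        em = sample_log_likelihood(grid, demo_items, model="em2pl",
                                   effort=effort, cfg=cfg)
        plain = sample_log_likelihood(grid, demo_items, model="2pl")
        assert em == pytest.approx(plain, abs=1e-9)

    def test_empty_grid_is_zero(self, demo_items):
        assert sample_log_likelihood(np.empty((0, 7)), demo_items) == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        items = items_from_arrays([1.0, 1.4, 0.8], [-1.0, 0.2, 1.1])
        grid = rng.integers(0, 2, size=(5, 3)).astype(float)
        total = sample_log_likelihood(grid, items)
        expected = 0.0
        for row in grid:
            theta = mle_theta(row, items).theta
            for y, it in zip(row, items):
                p = 1 / (1 + np.exp(-it.a * (theta - it.b)))
                p = min(max(p, 1e-6), 1 - 1e-6)
                expected += y * np.log(p) + (1 - y) * np.log(1 - p)
        assert total == pytest.approx(expected, abs=1e-9)
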
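import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import bptraj as bt
from bptraj.gbtm import (
    GBTMModel,
    adequacy,
    cnorm_obs_loglik,
    e_step,
    fit_gbtm,
    information_criteria,
    m_step,
    mixture_loglik,
    patient_group_loglik,
)
from bptraj.series import BPSeries, CensoringBounds
from bptraj.trajectories import TrajectoryShape


def _make_model(shapes, pi, sigma, n=10, bounds=None):
    pi = np.asarray(pi, dtype=float)
    theta = np.log(pi / pi[0])
    k = sum(s.order + 1 for s in shapes) + (len(pi) - 1) + 1
    llf = 0.0
    aic, bic = information_criteria(llf, k, n)
    return GBTMModel(len(pi), tuple(shapes), theta, pi, sigma,
                     bounds or CensoringBounds(), llf, n, k, aic, bic)


class TestCnormLoglik:
    def test_standard_normal_mode(self):
        assert cnorm_obs_loglik(0.0, 0.0, 1.0) == pytest.approx(-0.5 * math.log(2 * math.pi))
        assert cnorm_obs_loglik(0.0, 0.0, 1.0) == pytest.approx(-0.918939, abs=1e-6)

    def test_left_censored_at_the_mean_gives_log_half(self):
        b = CensoringBounds(lower=100.0)
        assert cnorm_obs_loglik(100.0, 100.0, 1.0, b) == pytest.approx(math.log(0.5))

    def test_interior_value_matches_closed_form(self):
        # N(120, 10^2) density at 130: -0.5*ln(2*pi*100) - 0.5
        expected = -0.5 * math.log(2 * math.pi * 100.0) - 0.5
        assert cnorm_obs_loglik(130.0, 120.0, 10.0) == pytest.approx(expected)
        assert expected == pytest.approx(-3.721524, abs=1e-6)

    def test_right_censoring_uses_survival_mass(self):
        b = CensoringBounds(upper=180.0)
        from scipy.stats import norm
        got = cnorm_obs_loglik(180.0, 170.0, 5.0, b)
        assert got == pytest.approx(norm.logsf(2.0))

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            cnorm_obs_loglik(0.0, 0.0, 0.0)


class TestPatientGroupLoglik:
    def test_single_observation_at_trajectory_value(self):
        s = BPSeries("p", "SBP", [1.0], [120.0])
        shape = TrajectoryShape((120.0,))
        assert patient_group_loglik(s, shape, 1.0) == pytest.approx(-0.918939, abs=1e-6)

    def test_additivity_over_observations(self):
        shape = TrajectoryShape((120.0, 1.0))
        one = BPSeries("p", "SBP", [2.0], [123.0])
        two = BPSeries("p", "SBP", [2.0, 3.0], [123.0, 120.0])
        extra = BPSeries("p", "SBP", [3.0], [120.0])
        assert patient_group_loglik(two, shape, 4.0) == pytest.approx(
            patient_group_loglik(one, shape, 4.0) + patient_group_loglik(extra, shape, 4.0)
        )

    def test_matches_per_point_hand_sum(self):
        shape = TrajectoryShape((110.0, -2.0, 0.1))
        s = BPSeries("p", "SBP", [0.0, 5.0, 20.0], [112.0, 101.0, 105.0])
        hand = sum(
            cnorm_obs_loglik(y, 110.0 - 2.0 * t + 0.1 * t**2, 6.0)
            for t, y in zip(s.times, s.values)
        )
        assert patient_group_loglik(s, shape, 6.0) == pytest.approx(hand, abs=1e-12)


class TestMixtureLoglik:
    def _toy_data(self, rng, n=5):
        grid = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        return [
            BPSeries(f"p{i}", "SBP", grid, 130 + rng.normal(0, 10, size=5))
            for i in range(n)
        ]

    def test_single_group_reduces_to_plain_sum(self):
        rng = np.random.default_rng(0)
        data = self._toy_data(rng)
        shape = TrajectoryShape((130.0, -0.5))
        model = _make_model([shape], [1.0], 8.0)
        direct = sum(patient_group_loglik(s, shape, 8.0) for s in data)
        assert mixture_loglik(data, model) == pytest.approx(direct)

    def test_degenerate_weights_ignore_empty_group(self):
        rng = np.random.default_rng(1)
        data = self._toy_data(rng)
        s1, s2 = TrajectoryShape((130.0,)), TrajectoryShape((170.0,))
        two = _make_model([s1, s2], [1.0, 0.0], 8.0)
        one = _make_model([s1], [1.0], 8.0)
        assert mixture_loglik(data, two) == pytest.approx(mixture_loglik(data, one))

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        data = self._toy_data(rng)
        shapes = [TrajectoryShape((125.0, 0.3)), TrajectoryShape((140.0, -0.2))]
        model = _make_model(shapes, [0.3, 0.7], 9.0)
        naive = sum(
            math.log(sum(
                p * math.exp(patient_group_loglik(s, sh, 9.0))
                for p, sh in zip(model.pi, shapes)
            ))
            for s in data
        )
        assert mixture_loglik(data, model) == pytest.approx(naive, abs=1e-10)


class TestEStep:
    def test_single_group_posteriors_are_one(self):
        data = [BPSeries("p0", "SBP", [0.0, 12.0], [120.0, 118.0])]
        model = _make_model([TrajectoryShape((120.0,))], [1.0], 5.0, n=1)
        post = e_step(data, model)
        assert np.allclose(post.probs, [[1.0]])
        assert post.assignments.tolist() == [1]

    def test_identical_shapes_give_uniform_posteriors_and_low_label_ties(self):
        data = [BPSeries("p0", "SBP", [0.0, 12.0], [120.0, 118.0])]
        sh = TrajectoryShape((120.0,))
        model = _make_model([sh, sh], [0.5, 0.5], 5.0, n=1)
        post = e_step(data, model)
        assert np.allclose(post.probs, [[0.5, 0.5]])
        assert post.assignments.tolist() == [1]  # tie broken to the lowest label

    def test_likelihood_ratio_hand_example(self):
        # one reading y=100 under mu=(100,160), sigma=10: z = (0, -6),
        # posterior_1 = 1 / (1 + exp(-(36-0)/2)) = 1/(1+exp(-18))
        data = [BPSeries("p0", "SBP", [1.0], [100.0])]
        model = _make_model([TrajectoryShape((100.0,)), TrajectoryShape((160.0,))],
                            [0.5, 0.5], 10.0, n=1)
        post = e_step(data, model)
        assert post.probs[0, 0] == pytest.approx(1.0 / (1.0 + math.exp(-18.0)), rel=1e-12)

    def test_rows_normalised(self, small_cohort):
        series = small_cohort.series("SBP")[:30]
        shapes, probs = bt.trajectories.group_table("SBP")
        model = _make_model(shapes, probs, 8.0, n=30)
        post = e_step(series, model)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((post.probs >= 0) & (post.probs <= 1))


class TestMStep:
    def test_all_mass_on_one_group_recovers_noiseless_line(self):
        grid = np.linspace(0.0, 24.0, 9)
        data = [BPSeries("p0", "SBP", grid, 100.0 + 2.0 * grid),
                BPSeries("p1", "SBP", grid, 100.0 + 2.0 * grid)]
        W = np.array([[1.0], [1.0]])
        shapes, sigma, theta = m_step(data, W, orders=[1])
        assert shapes[0].coefficients == pytest.approx((100.0, 2.0), abs=1e-9)
        assert sigma == pytest.approx(0.5)  # floored at sigma_min

    def test_symmetric_posteriors_give_identical_groups(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0.0, 24.0, 9)
        data = [BPSeries(f"p{i}", "SBP", grid, 130 + rng.normal(0, 5, 9)) for i in range(6)]
        W = np.full((6, 2), 0.5)
        shapes, sigma, theta = m_step(data, W, orders=[2, 2])
        assert shapes[0].coefficients == pytest.approx(shapes[1].coefficients)

    def test_weighted_fit_equals_replication_oracle(self):
        # weights 0.25/0.75 == replicating the series 1x and 3x, unweighted
        rng = np.random.default_rng(4)
        grid = np.linspace(0.0, 24.0, 7)
        y1 = 120 + rng.normal(0, 5, 7)
        y2 = 150 + rng.normal(0, 5, 7)
        data = [BPSeries("a", "SBP", grid, y1), BPSeries("b", "SBP", grid, y2)]
        W = np.array([[0.25, 0.75], [0.75, 0.25]])
        shapes, _, _ = m_step(data, W, orders=[1, 1])
        # replication oracle for group 1: series a once, series b three times
        X = np.vander(np.tile(grid, 4), 2, increasing=True)
        yy = np.concatenate([y1, y2, y2, y2])
        beta = np.linalg.lstsq(X, yy, rcond=None)[0]
        assert shapes[0].coefficients == pytest.approx(tuple(beta), abs=1e-8)

    def test_singular_design_raises(self):
        data = [BPSeries("p0", "SBP", [1.0, 2.0], [120.0, 121.0])]
        W = np.array([[1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            m_step(data, W, orders=[4])


class TestInformationCriteria:
    def test_closed_form(self):
        aic, bic = information_criteria(0.0, 3, 100)
        assert aic == pytest.approx(6.0)
        assert bic == pytest.approx(3 * math.log(100))
        assert bic == pytest.approx(13.815511, abs=1e-6)

    def test_zero_params_equal(self):
        aic, bic = information_criteria(-123.4, 0, 50)
        assert aic == bic == pytest.approx(246.8)

    def test_bic_penalty_gap_at_cohort_size(self):
        a1, b1 = information_criteria(-100.0, 5, 353)
        a2, b2 = information_criteria(-100.0, 6, 353)
        assert b2 - b1 == pytest.approx(math.log(353))
        assert b2 - b1 == pytest.approx(5.8665, abs=1e-4)


class TestAdequacy:
    def _posterior(self, probs):
        probs = np.asarray(probs, dtype=float)
        from bptraj.gbtm import PosteriorMatrix
        return PosteriorMatrix(tuple(f"p{i}" for i in range(len(probs))),
                               probs, np.argmax(probs, axis=1) + 1)

    def test_single_group_trivially_passes(self):
        model = _make_model([TrajectoryShape((120.0,))], [1.0], 5.0, n=4)
        post = self._posterior(np.ones((4, 1)))
        rep = adequacy(model, post)
        assert rep.group_shares == pytest.approx([1.0])
        assert rep.appa == pytest.approx([1.0])
        assert rep.passes

    def test_tiny_group_fails_five_percent_rule(self):
        # 100 patients, 4 modally in group 2 -> share 0.04 < 0.05
        probs = np.zeros((100, 2))
        probs[:96, 0] = 1.0
        probs[96:, 1] = 1.0
        model = _make_model([TrajectoryShape((120.0,)), TrajectoryShape((160.0,))],
                            [0.96, 0.04], 5.0, n=100)
        rep = adequacy(model, self._posterior(probs))
        assert not rep.passes_min_share
        assert not rep.passes

    def test_low_appa_fails_point_seven_rule(self):
        probs = np.array([[0.69, 0.31]] * 10 + [[0.2, 0.8]] * 10)
        model = _make_model([TrajectoryShape((120.0,)), TrajectoryShape((160.0,))],
                            [0.5, 0.5], 5.0, n=20)
        rep = adequacy(model, self._posterior(probs))
        assert rep.appa[0] == pytest.approx(0.69)
        assert not rep.passes_appa


class TestFitGBTM:
    def test_one_group_equals_polynomial_mle(self, small_cohort):
        series = small_cohort.series("SBP")[:40]
        model, post = fit_gbtm(series, 1, orders=2, n_starts=1, seed=0)
        t = np.concatenate([s.times for s in series])
        y = np.concatenate([s.values for s in series])
        beta = np.linalg.lstsq(np.vander(t, 3, increasing=True), y, rcond=None)[0]
        assert model.shapes[0].coefficients == pytest.approx(tuple(beta), abs=1e-8)
        resid = y - np.vander(t, 3, increasing=True) @ beta
        assert model.sigma == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-6)
        assert np.all(post.probs == 1.0)

    def test_recovers_two_well_separated_flat_groups(self, flat_two_group_series):
        series, truth = flat_two_group_series
        model, post = fit_gbtm(series, 2, orders=0, n_starts=3, seed=0)
        intercepts = [s.coefficients[0] for s in model.shapes]
        assert intercepts[0] == pytest.approx(120.0, abs=1.0)
        assert intercepts[1] == pytest.approx(160.0, abs=1.0)
        assert model.pi[0] == pytest.approx(np.mean(truth == 1), abs=0.05)
        assert adjusted_rand_score(truth, post.assignments) > 0.95

    def test_refit_with_same_seed_is_bit_identical(self, flat_two_group_series):
        series, _ = flat_two_group_series
        m1, p1 = fit_gbtm(series, 2, orders=1, n_starts=2, seed=5)
        m2, p2 = fit_gbtm(series, 2, orders=1, n_starts=2, seed=5)
        assert m1.shapes == m2.shapes
        assert m1.sigma == m2.sigma
        assert np.array_equal(p1.probs, p2.probs)

    def test_em_loglik_is_monotone(self, small_cohort):
        series = small_cohort.series("SBP")
        res = bt.GroupTrajectoryModel(series, 3, orders=2).fit(n_starts=2, seed=3)
        h = np.diff(res.loglik_history)
        assert np.all(h >= -1e-8)

    def test_pi_and_posterior_rows_sum_to_one(self, small_cohort):
        series = small_cohort.series("DBP")
        model, post = fit_gbtm(series, 3, orders=2, n_starts=2, seed=2)
        assert model.pi.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(model.pi, np.exp(model.theta) / np.exp(model.theta).sum())

    def test_groups_labelled_by_ascending_mean_trajectory(self, small_cohort):
        series = small_cohort.series("SBP")
        model, _ = fit_gbtm(series, 3, orders=2, n_starts=2, seed=9)
        grid = np.linspace(0, 24, 37)
        means = [np.mean(bt.evaluate_trajectory(s, grid)) for s in model.shapes]
        assert means == sorted(means)

    def test_free_parameter_count(self, small_cohort):
        series = small_cohort.series("SBP")[:30]
        model, _ = fit_gbtm(series, 2, orders=[2, 3], n_starts=2, seed=0)
        # (2+1) + (3+1) + (J-1) + sigma = 9
        assert model.n_free_params == 9
        assert model.aic == pytest.approx(2 * 9 - 2 * model.log_likelihood)

    def test_censored_fit_handles_bounded_readings(self):
        # readings clipped at 140: censored fit recovers a mean above naive
        rng = np.random.default_rng(8)
        grid = np.linspace(0, 24, 9)
        data = []
        for i in range(60):
            y = np.minimum(135.0 + rng.normal(0, 10, 9), 140.0)
            data.append(BPSeries(f"p{i}", "SBP", grid, y))
        bounds = CensoringBounds(upper=140.0)
        model, _ = fit_gbtm(data, 1, orders=0, bounds=bounds, n_starts=1, seed=0)
        naive, _ = fit_gbtm(data, 1, orders=0, n_starts=1, seed=0)
        assert model.shapes[0].coefficients[0] > naive.shapes[0].coefficients[0]
        assert model.shapes[0].coefficients[0] == pytest.approx(135.0, abs=2.0)


class TestSelectModel:
    def test_flat_single_trajectory_prefers_small_models(self, flat_two_group_series):
        # one true flat group: candidates above J=2 fail adequacy or lose on BIC
        rng = np.random.default_rng(12)
        grid = np.linspace(0, 24, 13)
        data = [BPSeries(f"p{i}", "SBP", grid, 130 + rng.normal(0, 6, 13))
                for i in range(120)]
        sel = bt.select_model(data, j_range=range(2, 5), orders=1, n_starts=2,
                              tol=1e-6, seed=0)
        # with no real structure the adequacy screen rejects the spurious splits
        assert not sel.adequate or sel.chosen == 2

    def test_same_seed_reruns_identically(self, small_cohort):
        series = small_cohort.series("DBP")
        s1 = bt.select_model(series, j_range=range(2, 5), orders=2, n_starts=2,
                             tol=1e-6, seed=4)
        s2 = bt.select_model(series, j_range=range(2, 5), orders=2, n_starts=2,
                             tol=1e-6, seed=4)
        assert s1.chosen == s2.chosen
        assert s1.trace.equals(s2.trace)

    def test_prune_policy_drops_insignificant_quartic_terms(self):
        # truly linear groups: pruning should cut the fitted degree below 4
        rng = np.random.default_rng(21)
        grid = np.linspace(0, 24, 13)
        data = []
        for i in range(150):
            mu = 120.0 if i % 2 else 155.0
            data.append(BPSeries(f"p{i}", "SBP", grid,
                                 mu - 0.3 * grid + rng.normal(0, 5, 13)))
        sel = bt.select_model(data, j_range=[2], orders=4, order_policy="prune",
                              n_starts=2, tol=1e-6, seed=0)
        orders = [s.order for s in sel.result.shapes]
        assert max(orders) < 4
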
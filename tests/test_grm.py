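import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irtval import (BankSpec, GrmFitConfig, ItemBank, ResponseMatrix,
                    SimulationDesign, ValidationError, fit_grm,
                    item_information, prob_categories, quadrature,
                    score_theta, eap_scores, simulate_dataset)
from irtval import test_information as total_information
from irtval.grm import marginal_loglik


class TestProbCategories:
    def test_cumulative_difference_oracle(self):
        """Category probabilities equal finite differences of independently
        computed cumulative logistic curves."""
        a, b, theta = 2.0, [-1.0, 0.0, 1.0, 2.0], 0.0
        pstar = [1.0] + [1.0 / (1.0 + math.exp(-a * (theta - bk)))
                         for bk in b] + [0.0]
        expected = [pstar[k] - pstar[k + 1] for k in range(5)]
        assert np.allclose(prob_categories(a, b, theta), expected, atol=1e-12)

    def test_dichotomous_symmetry_at_threshold(self):
        assert np.allclose(prob_categories(1.7, [0.3], 0.3), [0.5, 0.5])

    def test_limits(self):
        p_low = prob_categories(2.0, [-1, 0, 1], -50.0)
        p_high = prob_categories(2.0, [-1, 0, 1], 50.0)
        assert np.allclose(p_low, [1, 0, 0, 0], atol=1e-12)
        assert np.allclose(p_high, [0, 0, 0, 1], atol=1e-12)

    @given(a=st.floats(0.3, 5.0), b1=st.floats(-3, 2),
           gap=st.floats(0.1, 1.5))
    @settings(deadline=None, max_examples=50)
    def test_sums_to_one_on_effective_range(self, a, b1, gap):
        b = [b1, b1 + gap, b1 + 2 * gap]
        p = prob_categories(a, b, np.linspace(-8, 8, 33))
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-12)


class TestInformation:
    def test_derivative_matches_central_difference(self):
        a, b = 2.0, np.array([-1.0, 0.0, 1.0, 2.0])
        h = 1e-5
        for theta in (-1.3, 0.0, 0.8):
            dp_num = (prob_categories(a, b, theta + h)
                      - prob_categories(a, b, theta - h)) / (2 * h)
            pstar = 1.0 / (1.0 + np.exp(-a * (theta - b)))
            w = np.concatenate([[0.0], pstar * (1 - pstar), [0.0]])
            dp = a * (w[:-1] - w[1:])
            assert np.max(np.abs(dp - dp_num)) < 1e-6

    def test_vanishes_in_the_tails(self):
        assert item_information(2.5, [-1, 0, 1], -40.0) < 1e-10
        assert item_information(2.5, [-1, 0, 1], 40.0) < 1e-10

    def test_additive_over_items(self, toy_bank):
        theta = 0.4
        total = sum(item_information(toy_bank.slopes[i],
                                     toy_bank.thresholds[i], theta)
                    for i in range(toy_bank.n_items))
        assert np.isclose(total_information(toy_bank, theta), total)


class TestFitGrm:
    def test_parameter_recovery(self, recovery_fit):
        rm, bank, theta, est = recovery_fit
        slope_rmse = np.sqrt(np.mean((est.bank.slopes - bank.slopes) ** 2))
        bt = np.concatenate(bank.thresholds)
        be = np.concatenate(est.bank.thresholds)
        thr_rmse = np.sqrt(np.mean((be - bt) ** 2))
        assert slope_rmse < 0.35
        assert thr_rmse < 0.15
        assert np.corrcoef(est.bank.slopes, bank.slopes)[0, 1] > 0.95
        assert np.corrcoef(be, bt)[0, 1] > 0.95

    def test_loglik_monotone_and_converged(self, recovery_fit):
        est = recovery_fit[3]
        hist = np.array(est.ll_history)
        assert np.all(np.diff(hist) >= -1e-8)
        assert est.converged

    def test_fitted_thresholds_strictly_increasing(self, recovery_fit):
        for b in recovery_fit[3].bank.thresholds:
            assert np.all(np.diff(b) > 0)

    def test_parameter_ses_present_and_positive(self, recovery_fit):
        ses = recovery_fit[3].param_se
        assert set(ses) == set(recovery_fit[1].item_ids)
        for d in ses.values():
            assert d["slope"] > 0
            assert all(s > 0 for s in d["thresholds"])

    def test_two_item_marginal_likelihood_vs_brute_force(self):
        """Marginal likelihood of a 2-item dichotomous toy equals explicit
        per-pattern quadrature to 1e-8."""
        rng = np.random.default_rng(0)
        resp = rng.integers(1, 3, size=(60, 2))
        rm = ResponseMatrix(resp, [f"p{i}" for i in range(60)], ["a", "b"])
        est = fit_grm(rm, GrmFitConfig(compute_se=False))
        nodes, w = quadrature()
        pattern_lp = {}
        for patt in itertools.product((1, 2), repeat=2):
            like = np.ones_like(nodes)
            for i, x in enumerate(patt):
                like *= prob_categories(est.bank.slopes[i],
                                        est.bank.thresholds[i], nodes)[x - 1]
            pattern_lp[patt] = math.log(float(like @ w))
        brute = sum(pattern_lp[tuple(row)] for row in resp)
        assert abs(brute - est.log_likelihood) < 1e-8
        assert abs(brute - marginal_loglik(rm, est.bank)) < 1e-8

    def test_single_category_item_rejected(self):
        rm = ResponseMatrix(np.ones((50, 2), dtype=int), range(50),
                            ["a", "b"])
        with pytest.raises(ValidationError):
            fit_grm(rm)

    def test_unobserved_categories_collapsed_with_warning(self):
        rng = np.random.default_rng(1)
        resp = rng.choice([1, 2, 5], size=(200, 2))  # categories 3,4 unseen
        rm = ResponseMatrix(resp, range(200), ["a", "b"])
        with pytest.warns(UserWarning, match="collapsed"):
            est = fit_grm(rm, GrmFitConfig(compute_se=False, max_cycles=50))
        assert set(est.collapsed_items) == {"a", "b"}


class TestScoreTheta:
    def test_all_highest_clamped(self, toy_bank):
        est = score_theta([5, 5, 5, 5], toy_bank, "ML")
        assert est.theta == 4.0 and est.clamped
        est = score_theta([1, 1, 1, 1], toy_bank, "ML")
        assert est.theta == -4.0 and est.clamped

    def test_ml_matches_grid_search(self, toy_bank):
        rng = np.random.default_rng(3)
        grid = np.linspace(-4, 4, 10001)
        for _ in range(20):
            resp = rng.integers(1, 6, size=4)
            est = score_theta(resp, toy_bank, "ML")
            ll = np.zeros_like(grid)
            for i, x in enumerate(resp):
                ll += np.log(prob_categories(toy_bank.slopes[i],
                                             toy_bank.thresholds[i],
                                             grid)[x - 1])
            assert abs(est.theta - grid[np.argmax(ll)]) < 1e-3

    def test_eap_flat_likelihood_returns_prior_mean(self):
        flat = ItemBank(["i"], [1e-8], [[-1.0, 0.0, 1.0, 2.0]])
        est = score_theta([3], flat, "EAP")
        assert abs(est.theta) < 1e-6
        assert abs(est.se - 1.0) < 0.01  # posterior ~ prior N(0,1)

    def test_single_dichotomous_item_boundary(self):
        bank = ItemBank(["i"], [1.5], [[0.0]])
        lo = score_theta([1], bank, "ML")
        hi = score_theta([2], bank, "ML")
        assert lo.theta == -4.0 and lo.clamped
        assert hi.theta == 4.0 and hi.clamped

    def test_empty_pattern_rejected(self, toy_bank):
        with pytest.raises(ValidationError):
            score_theta([0, 0, 0, 0], toy_bank)

    def test_missing_items_ignored(self, toy_bank):
        full = score_theta([3, 3, 3, 3], toy_bank, "EAP")
        partial = score_theta([3, 0, 3, 0], toy_bank, "EAP")
        assert partial.n_items_used == 2
        assert partial.se > full.se

    def test_eap_scores_vectorised_matches_loop(self, toy_bank):
        rng = np.random.default_rng(5)
        resp = rng.integers(1, 6, size=(30, 4))
        rm = ResponseMatrix(resp, range(30), list(toy_bank.item_ids))
        vec = eap_scores(rm, toy_bank)
        loop = [score_theta(r, toy_bank, "EAP").theta for r in resp]
        assert np.allclose(vec, loop, atol=1e-10)

    def test_more_items_reduce_scoring_error(self):
        """Consistency: ML error with all 35 strong items is smaller than
        with the first 8, on the same simulated persons."""
        design = SimulationDesign(n_persons=150, seed=11)
        rm, bank, theta = simulate_dataset(design)
        err35, err8 = [], []
        sub = bank.subset(range(8))
        for row, t in zip(rm.responses, theta):
            e35 = score_theta(row, bank, "ML")
            e8 = score_theta(row[:8], sub, "ML")
            if not (e35.clamped or e8.clamped):
                err35.append(abs(e35.theta - t))
                err8.append(abs(e8.theta - t))
        assert np.mean(err35) < np.mean(err8)
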
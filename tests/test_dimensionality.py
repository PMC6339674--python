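import numpy as np
import pytest
from scipy.stats import norm

from irtval import (ResponseMatrix, ValidationError, efa_eigen_ratio,
                    local_dependence, one_factor_fit, polychoric_matrix)
from irtval.dimensionality import PolychoricResult, smooth_psd
from irtval.grm import cumulative_probs


def _rm(x):
    x = np.asarray(x, dtype=int)
    return ResponseMatrix(x, [f"p{i}" for i in range(x.shape[0])],
                          [f"q{j}" for j in range(x.shape[1])])


def _pc(corr):
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    return PolychoricResult(corr, [None] * p, list(range(p)),
                            np.ones((p, p), bool), np.full((p, p), np.nan))


class TestPolychoric:
    def test_identical_items_hit_upper_bound(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 6, size=(500, 1))
        res = polychoric_matrix(_rm(np.hstack([x, x])))
        assert res.corr[0, 1] >= 0.998

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 6, size=(20_000, 2))
        res = polychoric_matrix(_rm(x))
        assert abs(res.corr[0, 1]) < 0.02

    def test_recovers_generating_correlation(self):
        """Discretising a bivariate normal with rho = 0.6 at fixed cuts and
        re-estimating recovers rho within 0.02 at n = 50 000."""
        rng = np.random.default_rng(2)
        n = 50_000
        z1 = rng.standard_normal(n)
        z2 = 0.6 * z1 + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        cuts = [-1.0, -0.2, 0.5, 1.3]
        x = np.column_stack([np.digitize(z1, cuts), np.digitize(z2, cuts)]) + 1
        res = polychoric_matrix(_rm(x))
        assert 0.58 <= res.corr[0, 1] <= 0.62

    def test_single_category_item_named(self):
        x = np.column_stack([np.ones(100, int), 1 + (np.arange(100) % 5)])
        with pytest.raises(ValidationError, match="q0"):
            polychoric_matrix(_rm(x))

    def test_symmetric_and_person_order_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 5, size=(800, 4))
        res1 = polychoric_matrix(_rm(x))
        res2 = polychoric_matrix(_rm(x[rng.permutation(800)]))
        assert np.allclose(res1.corr, res1.corr.T)
        assert np.allclose(res1.corr, res2.corr, atol=1e-10)

    def test_cell_probabilities_sum_to_one(self):
        from irtval.dimensionality import _bvn_cell_probs
        p = _bvn_cell_probs(np.array([-1.0, 0.3]), np.array([-0.5, 0.8]), 0.4)
        assert abs(p.sum() - 1.0) < 1e-10


class TestOneFactorFit:
    def test_rank_one_structure_is_saturated(self):
        lam = np.array([0.8, 0.7, 0.6, 0.75, 0.65])
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        fit, loadings, residual = one_factor_fit(_pc(corr), n=1000)
        assert fit.cfi == 1.0
        assert fit.rmsea == 0.0
        assert fit.srmr < 1e-6
        assert np.allclose(np.abs(loadings), lam, atol=1e-4)
        assert np.max(np.abs(residual)) < 1e-6

    def test_identity_matrix_degenerate_baseline(self):
        fit, _, _ = one_factor_fit(_pc(np.eye(6)), n=500)
        assert fit.degenerate_baseline
        assert fit.cfi == 1.0

    def test_unidimensional_cohort_meets_fit_criteria(self, ability_cohort):
        rm = ability_cohort[0]
        pc = polychoric_matrix(rm)
        fit, _, residual = one_factor_fit(pc, rm.n_persons)
        assert fit.cfi > 0.95
        assert fit.tli > 0.95
        assert fit.srmr < 0.08
        ld = local_dependence(residual, rm.item_ids)
        assert ld.flagged_pairs == []

    def test_heywood_clamped_and_flagged(self):
        corr = np.array([[1.0, 0.999, 0.2],
                         [0.999, 1.0, 0.2],
                         [0.2, 0.2, 1.0]])
        fit, loadings, _ = one_factor_fit(_pc(corr), n=200)
        assert np.all(np.abs(loadings) <= 0.999)


class TestEigenRatio:
    @pytest.mark.parametrize("e1,e2,expected", [(27.3, 0.92, 29.7),
                                                (33.0, 1.44, 22.9)])
    def test_first_to_second_ratio(self, e1, e2, expected):
        """Reported eigenvalue pairs give the reported ratios to 1 d.p."""
        p = 8
        rest = np.full(p - 2, 0.4)
        spectrum = np.concatenate([[e1, e2], rest])
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((p, p)))
        mat = (q * spectrum) @ q.T
        _, ratio, _ = efa_eigen_ratio(mat)
        assert round(ratio, 1) == expected

    def test_identity_all_ones(self):
        eig, ratio, pct = efa_eigen_ratio(np.eye(7))
        assert np.allclose(eig, 1.0)
        assert ratio == 1.0
        assert np.isclose(pct, 1 / 7)

    def test_trace_preserved(self, ability_cohort):
        pc = polychoric_matrix(ability_cohort[0].subset_items(range(8)))
        eig, _, _ = efa_eigen_ratio(pc)
        assert abs(eig.sum() - 8) < 1e-8


class TestLocalDependence:
    def test_zero_residuals_no_flags(self):
        assert local_dependence(np.zeros((4, 4))).flagged_pairs == []

    def test_single_pair_flagged(self):
        res = np.zeros((4, 4))
        res[1, 3] = res[3, 1] = 0.25
        ld = local_dependence(res, ["a", "b", "c", "d"])
        assert ld.flagged_pairs == [("b", "d", 0.25)]

    def test_doublet_detected(self):
        """Two items sharing a nuisance factor beyond the common trait show
        a flagged residual correlation."""
        rng = np.random.default_rng(4)
        n = 3000
        theta = rng.standard_normal(n)
        nuis = rng.standard_normal(n)
        cols = []
        for j in range(6):
            t = theta if j < 4 else (theta + 1.2 * nuis) / np.sqrt(1 + 1.44)
            pstar = cumulative_probs(2.5, np.array([-1.0, -0.3, 0.4, 1.1]), t)
            u = rng.random(n)
            cols.append(1 + (u[None, :] < pstar).sum(axis=0))
        rm = _rm(np.column_stack(cols))
        pc = polychoric_matrix(rm)
        _, _, residual = one_factor_fit(pc, n)
        ld = local_dependence(residual, rm.item_ids)
        assert ("q4", "q5", pytest.approx(residual[4, 5])) in \
            [(a, b, pytest.approx(r)) for a, b, r in ld.flagged_pairs]


class TestSmoothing:
    def test_negative_eigenvalues_raised(self):
        corr = np.array([[1.0, 0.9, -0.9],
                         [0.9, 1.0, 0.9],
                         [-0.9, 0.9, 1.0]])  # indefinite
        sm = smooth_psd(corr)
        assert np.linalg.eigvalsh(sm).min() >= 0
        assert np.allclose(np.diag(sm), 1.0)
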
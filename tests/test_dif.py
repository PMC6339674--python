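import numpy as np
import pytest
from scipy.optimize import minimize

from irtval import (BankSpec, DIFEffect, SimulationDesign, ValidationError,
                    age_median_split, cumulative_logit_fit, dif_screen,
                    eap_scores, mcfadden_r2, null_loglik, simulate_dataset)


class TestCumulativeLogitFit:
    def test_intercept_only_closed_form(self):
        y = np.repeat([1, 2, 3], [20, 30, 50])
        fit = cumulative_logit_fit(y, np.zeros((100, 1)))
        closed = 20 * np.log(0.2) + 30 * np.log(0.3) + 50 * np.log(0.5)
        assert abs(fit.loglik - closed) < 1e-6
        assert abs(null_loglik(y) - closed) < 1e-12

    def test_matches_brute_force_on_toy_set(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = np.clip(np.round(x + rng.normal(size=20)), -1, 1) + 2
        fit = cumulative_logit_fit(y, x)

        def negll(params):  # free parameterisation, checked for ordering
            a1, a2, beta = params
            if a2 <= a1:
                return 1e10
            from scipy.special import expit
            c1 = expit(a1 - beta * x)
            c2 = expit(a2 - beta * x)
            p = np.select([y == 1, y == 2, y == 3],
                          [c1, c2 - c1, 1 - c2])
            return -np.sum(np.log(np.clip(p, 1e-300, None)))

        best = minimize(negll, [-1.0, 1.0, 0.0], method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12,
                                 "maxiter": 5000})
        assert abs(fit.loglik + best.fun) < 1e-6

    def test_null_effect_coefficient_near_zero(self):
        rng = np.random.default_rng(1)
        n = 10_000
        x = rng.normal(size=(n, 1))
        y = rng.integers(1, 5, size=n)  # independent of x
        fit = cumulative_logit_fit(y, x)
        assert abs(fit.beta[0]) < 0.05

    def test_matches_statsmodels(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        rng = np.random.default_rng(3)
        n = 500
        X = rng.normal(size=(n, 2))
        lat = X @ [0.8, -0.5] + rng.logistic(size=n)
        y = np.digitize(lat, [-1, 0, 1])
        fit = cumulative_logit_fit(y, X)
        sm = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        assert abs(fit.loglik - sm.llf) < 1e-6
        assert np.allclose(fit.beta, sm.params[:2], atol=1e-4)

    def test_single_category_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_logit_fit(np.ones(50), np.zeros((50, 1)))


@pytest.fixture(scope="module")
def dif_cohort():
    """n = 2000 (about 1000 per gender), one item with a 0.6 uniform shift."""
    eff = DIFEffect(item="item03", group_var="gender",
                    focal_level="female", uniform_shift=0.6)
    design = SimulationDesign(n_persons=2000,
                              bank_spec=BankSpec(n_items=10),
                              dif_spec=[eff], seed=11)
    rm, bank, theta = simulate_dataset(design)
    return rm, bank, eap_scores(rm, bank)


class TestDifScreen:
    def test_injected_uniform_shift_flagged(self, dif_cohort):
        rm, bank, thetas = dif_cohort
        res = dif_screen(rm, thetas, "gender")
        assert res.flagged_items == ["item03"]
        row = res.table.set_index("item_id").loc["item03"]
        assert row["classification"] == "uniform"
        assert row["delta_total"] >= 0.02

    def test_nesting_of_model_likelihoods(self, dif_cohort):
        rm, bank, thetas = dif_cohort
        res = dif_screen(rm, thetas, "gender")
        assert (res.table["r2_m2"] >= res.table["r2_m1"] - 1e-6).all()
        assert (res.table["r2_m3"] >= res.table["r2_m2"] - 1e-6).all()
        assert (res.table["delta_total"] >= -1e-6).all()

    def test_permuted_labels_show_no_dif(self, dif_cohort):
        rm, bank, thetas = dif_cohort
        rng = np.random.default_rng(5)
        shuffled = rm.covariates.copy()
        shuffled["gender"] = rng.permutation(shuffled["gender"].to_numpy())
        rm2 = type(rm)(rm.responses, rm.person_ids, rm.item_ids, shuffled)
        res = dif_screen(rm2, thetas, "gender")
        assert (res.table["delta_total"] < 0.02).all()

    def test_null_data_unflagged(self):
        rm, bank, _ = simulate_dataset(SimulationDesign(
            n_persons=1000, bank_spec=BankSpec(n_items=10), seed=23))
        res = dif_screen(rm, eap_scores(rm, bank), "gender")
        assert res.flagged_items == []

    def test_purification_converges(self, dif_cohort):
        rm, bank, thetas = dif_cohort
        res = dif_screen(rm, thetas, "gender", purify=True, bank=bank)
        assert res.purification_iterations <= 10
        assert res.flagged_items == ["item03"]

    def test_multilevel_nominal_grouping_runs(self, dif_cohort):
        rm, bank, thetas = dif_cohort
        res = dif_screen(rm, thetas, "region", items=["item01", "item02"])
        assert (res.table["delta_total"] < 0.02).all()

    def test_group_floor_enforced(self, dif_cohort):
        rm, bank, thetas = dif_cohort
        with pytest.raises(ValidationError, match="floor"):
            dif_screen(rm, thetas, "gender", min_group=1500)

    def test_unknown_covariate(self, dif_cohort):
        rm, bank, thetas = dif_cohort
        with pytest.raises(ValidationError):
            dif_screen(rm, thetas, "shoe_size")


class TestAgeMedianSplit:
    def test_basic_split(self):
        g = age_median_split([40, 53, 60])
        assert list(g.value_counts()) == [2, 1]
        assert set(g.cat.categories) == {"<=53", ">53"}

    def test_all_equal_ages_degenerate_downstream(self, dif_cohort):
        rm, bank, thetas = dif_cohort
        cov = rm.covariates.copy()
        cov["age_split"] = age_median_split(np.full(rm.n_persons, 50))
        rm2 = type(rm)(rm.responses, rm.person_ids, rm.item_ids, cov)
        with pytest.raises(ValidationError):
            dif_screen(rm2, thetas, "age_split")
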
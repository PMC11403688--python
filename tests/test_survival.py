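"""Tests for penalized Cox modeling, stratification and survival statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliomanet import survival as surv
from oracles import cox_lasso_oracle, cox_pll_brute, km_hand, logrank_hand


class TestPmax:
    @pytest.mark.parametrize(
        "events,expected", [(233, 24), (226, 23), (10, 1), (11, 2), (1, 1)]
    )
    def test_ten_events_per_variable_cap(self, events, expected):
        assert surv.compute_pmax(events) == expected

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            surv.compute_pmax(0)


class TestPartialLoglik:
    def test_null_model_closed_form(self):
        data = surv.SurvivalData(
            np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]),
            pd.DataFrame(np.zeros((3, 1)), columns=["x"]),
        )
        expected = -(np.log(3) + np.log(2) + np.log(1))
        assert surv.cox_partial_loglik(np.zeros(1), data) == pytest.approx(expected)

    def test_single_event_sample_is_zero(self):
        data = surv.SurvivalData(
            np.array([2.0]), np.array([1]), pd.DataFrame([[1.5]], columns=["x"])
        )
        assert surv.cox_partial_loglik(np.array([0.3]), data) == pytest.approx(0.0)

    def test_matches_brute_force_with_ties(self, rng):
        n, p = 25, 3
        X = pd.DataFrame(rng.standard_normal((n, p)))
        t = rng.integers(1, 8, size=n).astype(float)  # heavy ties
        e = rng.integers(0, 2, size=n)
        e[0] = 1
        data = surv.SurvivalData(t, e, X)
        beta = rng.standard_normal(p) * 0.5
        mine = surv.cox_partial_loglik(beta, data)
        brute = cox_pll_brute(beta, X.to_numpy(), t, e)
        assert mine == pytest.approx(brute, abs=1e-12)

    def test_penalty_subtracted(self, small_survival_data):
        beta = np.array([0.5, -0.5, 0.0, 0.0])
        full = surv.cox_partial_loglik(beta, small_survival_data)
        pen = surv.cox_penalized_loglik(beta, small_survival_data, lam=2.0)
        assert pen == pytest.approx(full - 2.0)


class TestCoxLassoPath:
    def test_zero_solution_at_lambda_max(self, small_survival_data):
        lam_max = surv.cox_lambda_max(small_survival_data)
        path = surv.cox_lasso_path(
            small_survival_data, lambda_grid=np.array([lam_max * 1.01, lam_max])
        )
        assert all(len(m.active_set) == 0 for m in path)

    def test_coefficient_enters_just_below_lambda_max(self, small_survival_data):
        lam_max = surv.cox_lambda_max(small_survival_data)
        path = surv.cox_lasso_path(
            small_survival_data, lambda_grid=np.array([lam_max, lam_max * 0.95])
        )
        assert len(path[1].active_set) >= 1

    def test_objective_matches_convex_oracle(self, rng):
        n, p = 40, 5
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"g{i}" for i in range(p)])
        beta = np.array([0.8, -0.8, 0.0, 0.0, 0.4])
        t = rng.exponential(1.0 / np.exp(X.to_numpy() @ beta))
        e = (rng.random(n) > 0.2).astype(int)
        data = surv.SurvivalData(t, e, X)
        lam_max = surv.cox_lambda_max(data, standardize=False)
        lam = lam_max / 2
        path = surv.cox_lasso_path(
            data, lambda_grid=np.array([lam_max, lam]), standardize=False
        )
        mine = surv.cox_penalized_loglik(path[-1].beta.to_numpy(), data, lam)
        _, best = cox_lasso_oracle(X.to_numpy(), t, e, lam)
        assert mine == pytest.approx(best, abs=1e-6)

    def test_unpenalized_limit_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n, p = 50, 2
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=["a", "b"])
        t = rng.exponential(1.0 / np.exp(0.7 * X["a"].to_numpy()))
        e = (rng.random(n) > 0.2).astype(int)
        data = surv.SurvivalData(t, e, X)
        path = surv.cox_lasso_path(
            data, lambda_grid=np.array([surv.cox_lambda_max(data), 1e-9])
        )
        df = X.copy()
        df["T"], df["E"] = t, e
        ref = CoxPHFitter().fit(df, "T", "E").params_
        np.testing.assert_allclose(path[-1].beta.to_numpy(), ref.to_numpy(), atol=1e-4)

    def test_kkt_residual_along_path(self, small_survival_data):
        path = surv.cox_lasso_path(small_survival_data, n_lambdas=20)
        for m in path[1:]:
            assert surv.cox_kkt_residual(m, small_survival_data) < 1e-4

    def test_active_set_matches_sksurv_coxnet(self, rng):
        """Cross-check the path against an independent elastic-net Cox solver."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        n, p = 80, 6
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"g{i}" for i in range(p)])
        beta = np.array([0.9, -0.9, 0.5, 0.0, 0.0, 0.0])
        t = rng.exponential(1.0 / np.exp(X.to_numpy() @ beta))
        e = (rng.random(n) > 0.2).astype(int)
        e[:2] = 1
        data = surv.SurvivalData(t, e, X)
        lam_max = surv.cox_lambda_max(data)
        lam = lam_max / 4
        path = surv.cox_lasso_path(data, lambda_grid=np.array([lam_max, lam]))
        cox = CoxnetSurvivalAnalysis(
            alphas=[lam / n], l1_ratio=1.0, tol=1e-9, normalize=False
        )
        y = np.array(
            [(bool(ev), ti) for ev, ti in zip(e, t)],
            dtype=[("event", bool), ("time", float)],
        )
        Xs = (X - X.mean()) / X.std(ddof=0)
        cox.fit(Xs.to_numpy(), y)
        ref = np.asarray(cox.coef_).ravel()
        mine_std = path[-1].beta.to_numpy() * X.std(ddof=0).to_numpy()
        np.testing.assert_allclose(mine_std, ref, atol=5e-3)


class TestSelectModel:
    def _path_with_sizes(self, sizes):
        models = []
        for i, s in enumerate(sizes):
            beta = pd.Series(0.0, index=[f"g{k}" for k in range(10)])
            beta.iloc[:s] = 1.0
            models.append(surv.CoxModel(beta=beta, lam=10.0 - i))
        return models

    def test_densest_model_under_cap(self):
        path = self._path_with_sizes([0, 2, 5, 9])
        assert len(surv.select_model(path, 5).active_set) == 5

    def test_cap_above_max_returns_densest(self):
        path = self._path_with_sizes([0, 2, 5, 9])
        assert len(surv.select_model(path, 100).active_set) == 9

    def test_pmax_zero_null_model_with_warning(self):
        path = self._path_with_sizes([0, 2])
        with pytest.warns(UserWarning):
            model = surv.select_model(path, 0)
        assert len(model.active_set) == 0


class TestPrognosticIndex:
    def test_zero_beta_gives_zero(self):
        X = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        model = surv.CoxModel(beta=pd.Series([0.0, 0.0], index=["a", "b"]), lam=1.0)
        assert surv.prognostic_index(X, model).iloc[0] == 0.0

    def test_dot_product(self):
        X = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        model = surv.CoxModel(beta=pd.Series([0.5, -1.0], index=["a", "b"]), lam=1.0)
        assert surv.prognostic_index(X, model).iloc[0] == pytest.approx(-1.5)
        assert surv.prognostic_index(2 * X, model).iloc[0] == pytest.approx(-3.0)

    def test_misaligned_features_rejected(self):
        X = pd.DataFrame([[1.0]], columns=["a"])
        model = surv.CoxModel(beta=pd.Series([0.5], index=["missing"]), lam=1.0)
        with pytest.raises(ValueError):
            surv.prognostic_index(X, model)


class TestKdeThreshold:
    def test_bimodal_minimum_between_modes(self):
        r = np.random.default_rng(3)
        pi = np.concatenate([r.normal(-2, 0.5, 250), r.normal(2, 0.5, 250)])
        assert -1 < surv.kde_threshold(pi) < 1

    def test_unimodal_falls_back_to_median(self):
        r = np.random.default_rng(4)
        pi = r.standard_normal(400)
        assert surv.kde_threshold(pi) == pytest.approx(np.median(pi))

    def test_imbalanced_mixture_not_median(self):
        r = np.random.default_rng(5)
        pi = np.concatenate([r.normal(-3, 0.3, 200), r.normal(1, 0.3, 600)])
        thr = surv.kde_threshold(pi)
        assert -2.5 < thr < 0.5
        assert abs(thr - np.median(pi)) > 0.3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            surv.kde_threshold(np.ones(50))
        with pytest.raises(ValueError):
            surv.kde_threshold(np.arange(5.0))


class TestStratify:
    def test_boundary_sample_is_low_risk(self):
        pi = pd.Series([0.0, 1.0, 2.0])
        strat = surv.stratify(pi, 1.0)
        assert strat.group.tolist() == ["LR", "LR", "HR"]

    def test_all_above_threshold(self):
        strat = surv.stratify(pd.Series([1.0, 2.0]), 0.0)
        assert (strat.group == "HR").all()

    def test_infinite_threshold_all_low_risk(self):
        strat = surv.stratify(pd.Series([1.0, 2.0]), np.inf)
        assert (strat.group == "LR").all()


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        data = surv.SurvivalData(
            np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]),
            pd.DataFrame(np.zeros((3, 1)), columns=["x"]),
        )
        curves = surv.km_estimate(data, np.array(["g", "g", "g"])).curves["g"]
        lookup = dict(zip(curves["time"], curves["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(1 / 3)  # censored at 3

    def test_matches_definition_oracle(self, small_survival_data):
        curves = surv.km_estimate(
            small_survival_data, np.array(["g"] * 50)
        ).curves["g"]
        lookup = dict(zip(curves["time"], curves["survival"]))
        for t, s in km_hand(small_survival_data.time, small_survival_data.event):
            assert lookup[t] == pytest.approx(s)

    def test_no_events_flat_curve(self):
        data = surv.SurvivalData(
            np.array([1.0, 2.0]), np.array([0, 0]),
            pd.DataFrame(np.zeros((2, 1)), columns=["x"]),
        )
        curves = surv.km_estimate(data, np.array(["g", "g"])).curves["g"]
        assert (curves["survival"] == 1.0).all()

    def test_monotone_nonincreasing_in_unit_interval(self, small_survival_data):
        curves = surv.km_estimate(small_survival_data, np.array(["g"] * 50))
        s = curves.curves["g"]["survival"].to_numpy()
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        data = surv.SurvivalData(t, e, pd.DataFrame(np.zeros((6, 1)), columns=["x"]))
        res = surv.logrank_test(data, np.array(["a"] * 3 + ["b"] * 3))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        groups = np.array(["A", "A", "B", "B"])
        data = surv.SurvivalData(t, e, pd.DataFrame(np.zeros((4, 1)), columns=["x"]))
        res = surv.logrank_test(data, groups)
        assert res.statistic == pytest.approx(logrank_hand(t, e, groups))

    def test_three_groups_rejected(self):
        data = surv.SurvivalData(
            np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]),
            pd.DataFrame(np.zeros((3, 1)), columns=["x"]),
        )
        with pytest.raises(ValueError):
            surv.logrank_test(data, np.array(["a", "b", "c"]))

    def test_strong_effect_detected(self, rng):
        n = 100
        X = pd.DataFrame(rng.standard_normal((n, 1)), columns=["g"])
        groups = np.where(X["g"] > 0, "HR", "LR")
        t = rng.exponential(1.0 / np.exp(2.0 * (groups == "HR")))
        data = surv.SurvivalData(t, np.ones(n, int), X)
        assert surv.logrank_test(data, groups).p_value < 1e-6
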
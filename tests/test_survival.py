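import numpy as np
import pandas as pd
import pytest

from oracles import (
    brute_force_auc,
    brute_force_cindex,
    brute_force_logrank,
    cox_score_test_no_ties,
)
from ticscore import (
    CollinearityError,
    DegenerateDataError,
    SeparationError,
    c_index,
    calibration_table,
    chisquare_independence,
    compare_td_auc,
    cox_fit,
    dxy_optimism,
    km_fit,
    logrank_test,
    mann_whitney_u,
    spearman_corr,
    td_auc_ipcw,
    youden_optimal_cutoff,
)


def _sim_two_group(rng, n=2000, log_hr=np.log(0.5), censor_frac=0.3):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0, n) / np.exp(log_hr * x)
    c = np.quantile(t, 1 - censor_frac) * rng.uniform(0.3, 3.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return pd.DataFrame({"x": x}), time + 1e-9, event


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_fit([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(5.0)[0] == 1.0

    def test_hand_product_limit(self):
        km = km_fit([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_allclose(km.at_risk, [4, 3, 2, 1])

    def test_trailing_censor_adds_no_drop(self):
        b = km_fit([1.0, 2.0, 3.0, 9.0], [1, 1, 1, 0])
        np.testing.assert_allclose(b.survival, [0.75, 0.5, 0.25])
        # curve stays flat through and beyond the trailing censor time
        assert b.survival_at(8.9)[0] == pytest.approx(0.25)
        assert b.survival_at(20.0)[0] == pytest.approx(0.25)

    def test_survival_non_increasing_starts_at_one(self, rng):
        t = rng.exponential(10, 60) + 0.01
        e = rng.integers(0, 2, 60)
        if e.sum() == 0:
            e[0] = 1
        km = km_fit(t, e)
        assert km.survival_at(0.0)[0] == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_o_minus_e(self, rng):
        t = np.round(rng.exponential(5, 30), 1) + 0.1  # with ties
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        e[:4] = 1
        g[:2] = 0
        g[2:4] = 1
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(brute_force_logrank(t, e, g), rel=1e-10)

    def test_equals_cox_score_test_without_ties(self, rng):
        n = 80
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n)
        e[:3] = 1
        x[:2] = 1
        x[2] = 0
        chi2, _ = logrank_test(t, e, x)
        assert chi2 == pytest.approx(cox_score_test_no_ties(t, e, x), abs=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestCox:
    def test_hand_solvable_instance(self):
        # times 1,2,3 all events, x=(0,1,0): betahat = 0.5*ln 2
        fit = cox_fit(pd.DataFrame({"x": [0.0, 1.0, 0.0]}), [1.0, 2.0, 3.0], [1, 1, 1])
        assert fit.coef["x"] == pytest.approx(0.5 * np.log(2), abs=1e-6)
        assert fit.hr["x"] == pytest.approx(np.sqrt(2), abs=1e-6)
        lo, hi = fit.summary.loc["x", ["ci_lo", "ci_hi"]]
        assert lo < fit.hr["x"] < hi

    def test_collinear_columns_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        X["y"] = 2 * X["x"]
        with pytest.raises(CollinearityError):
            cox_fit(X, [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])

    def test_constant_column_rejected(self):
        with pytest.raises(CollinearityError):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1.0, 2.0, 3.0], [1, 1, 1])

    def test_perfect_separation_detected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        x = pd.DataFrame({"x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]})
        with pytest.raises(SeparationError, match="x"):
            cox_fit(x, t, e)

    def test_two_group_simulation_recovers_hr(self, rng):
        X, t, e = _sim_two_group(rng)
        fit = cox_fit(X, t, e)
        assert 0.45 <= fit.hr["x"] <= 0.56

    def test_weibull_ph_parameter_recovery(self, rng):
        # Weibull baseline, ~30% censoring, two continuous covariates
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        beta = np.array([0.7, -1.0])
        lp = X.to_numpy() @ beta
        u = rng.uniform(size=n)
        t_ev = (-np.log(u) / (0.01 * np.exp(lp))) ** (1 / 1.5)
        c = rng.exponential(np.quantile(t_ev, 0.8), n)
        time = np.minimum(t_ev, c) + 1e-9
        event = (t_ev <= c).astype(int)
        assert 0.15 < 1 - event.mean() < 0.45
        fit = cox_fit(X, time, event)
        assert abs(fit.coef["a"] - 0.7) < 0.1
        assert abs(fit.coef["b"] + 1.0) < 0.1


class TestConcordance:
    def test_perfect_and_constant(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        assert c_index(-t, t, e) == pytest.approx(1.0)
        assert c_index(np.zeros(4), t, e) == pytest.approx(0.5)

    def test_matches_pair_enumeration(self, rng):
        n = 25
        t = rng.exponential(5, n) + 0.01
        e = rng.integers(0, 2, n)
        e[:5] = 1
        s = np.round(rng.normal(size=n), 1)  # ties in score
        assert c_index(s, t, e) == pytest.approx(
            brute_force_cindex(s, t, e), abs=1e-12
        )

    def test_negation_complements_on_tie_free_data(self, rng):
        n = 30
        t = rng.exponential(5, n) + 0.01
        e = np.ones(n, int)
        s = rng.normal(size=n)
        assert c_index(s, t, e) + c_index(-s, t, e) == pytest.approx(1.0, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(DegenerateDataError):
            c_index([1.0, 2.0], [5.0, 5.0], [0, 0])


class TestDxyOptimism:
    def test_dxy_is_2c_minus_1_for_apparent(self, rng):
        X, t, e = _sim_two_group(rng, n=150)
        apparent, _ = dxy_optimism(X, t, e, B=1, seed=0)
        fit = cox_fit(X, t, e)
        lp = fit.linear_predictor(X)
        assert apparent == pytest.approx(2 * c_index(lp, t, e) - 1, abs=1e-12)

    def test_corrected_below_apparent_for_overfit_model(self, rng):
        # 6 pure-noise covariates on a small sample overfit by construction
        n = 70
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"z{i}" for i in range(6)])
        t = rng.exponential(10, n) + 0.01
        e = rng.integers(0, 2, n)
        e[:10] = 1
        apparent, corrected = dxy_optimism(X, t, e, B=60, seed=3)
        assert corrected < apparent

    def test_single_rep_returns_finite(self, rng):
        X, t, e = _sim_two_group(rng, n=80)
        apparent, corrected = dxy_optimism(X, t, e, B=1, seed=1)
        assert np.isfinite(apparent) and np.isfinite(corrected)


class TestTdAucIpcw:
    def test_perfect_marker_no_censoring(self):
        t = np.array([1.0, 2.0, 10.0, 12.0])
        e = np.array([1, 1, 1, 1])
        s = np.array([5.0, 4.0, 1.0, 0.0])
        assert td_auc_ipcw(s, t, e, 5.0) == pytest.approx(1.0)

    def test_constant_marker_half(self):
        t = np.array([1.0, 2.0, 10.0, 12.0])
        e = np.array([1, 1, 1, 1])
        assert td_auc_ipcw(np.ones(4), t, e, 5.0) == pytest.approx(0.5)

    def test_no_censoring_equals_mann_whitney(self, rng):
        n = 120
        t = rng.exponential(10, n) + 0.01
        e = np.ones(n, int)
        s = np.round(rng.normal(size=n), 1)
        tau = float(np.median(t))
        cases = s[(t <= tau)]
        controls = s[t > tau]
        assert td_auc_ipcw(s, t, e, tau) == pytest.approx(
            brute_force_auc(cases, controls), abs=1e-12
        )

    def test_agrees_with_sksurv_under_censoring(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 200
        ev = rng.exponential(40, n)
        cz = rng.exponential(60, n)
        time = np.minimum(ev, cz) + 1e-9
        e = (ev <= cz).astype(int)
        s = -ev + rng.normal(0, 15, n)
        y = Surv.from_arrays(e.astype(bool), time)
        for tau in (15.0, 30.0):
            theirs, _ = cumulative_dynamic_auc(y, y, s, [tau])
            assert td_auc_ipcw(s, time, e, tau) == pytest.approx(
                theirs[0], abs=1e-10
            )

    def test_no_cases_or_controls_rejected(self):
        t = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            td_auc_ipcw([1.0, 2.0, 3.0], t, [1, 1, 1], 0.5)
        with pytest.raises(DegenerateDataError):
            td_auc_ipcw([1.0, 2.0, 3.0], t, [1, 1, 1], 10.0)


class TestCompareTdAuc:
    def test_identical_markers_null_result(self, rng):
        X, t, e = _sim_two_group(rng, n=150)
        s = rng.normal(size=150)
        delta, p = compare_td_auc(s, s.copy(), t, e, float(np.median(t)),
                                  B=100, seed=0)
        assert delta == 0.0
        assert p == pytest.approx(1.0)

    def test_informative_vs_constant_marker(self, rng):
        n = 500
        ev = rng.exponential(40, n)
        time = ev + 1e-9
        e = np.ones(n, int)
        informative = -ev + rng.normal(0, 5, n)
        constant_plus_eps = rng.normal(0, 1e-12, n)  # effectively uninformative
        delta, p = compare_td_auc(informative, constant_plus_eps, time, e,
                                  30.0, B=200, seed=1)
        assert delta > 0.2
        assert p < 0.01


class TestCalibration:
    def test_bins_partition_sample(self, rng):
        X, t, e = _sim_two_group(rng, n=300)
        X["z"] = rng.normal(size=300)
        tbl = calibration_table(X, t, e, horizon=float(np.median(t)), n_bins=4)
        assert tbl["n"].sum() == 300

    def test_single_bin_rejected(self, rng):
        X, t, e = _sim_two_group(rng, n=50)
        with pytest.raises(ValueError):
            calibration_table(X, t, e, horizon=1.0, n_bins=1)

    def test_well_specified_model_calibrates(self, rng):
        n = 1200
        X = pd.DataFrame({"a": rng.normal(size=n)})
        lp = 0.8 * X["a"].to_numpy()
        t_ev = rng.exponential(1.0, n) / (0.05 * np.exp(lp))
        c = rng.exponential(np.quantile(t_ev, 0.8), n)
        time = np.minimum(t_ev, c) + 1e-9
        event = (t_ev <= c).astype(int)
        tbl = calibration_table(X, time, event,
                                horizon=float(np.quantile(time, 0.4)), n_bins=4)
        assert (np.abs(tbl["predicted"] - tbl["observed"]) < 0.08).all()


class TestYouden:
    def test_perfect_separation(self):
        res = youden_optimal_cutoff([1.0, 2.0, 8.0, 9.0], [0, 0, 1, 1])
        assert res.j == pytest.approx(1.0)
        assert 2.0 < res.cutoff < 8.0

    def test_matches_exhaustive_search(self, rng):
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.05])
        y = np.array([0, 0, 1, 1, 1, 0])
        res = youden_optimal_cutoff(s, y)
        uniq = np.unique(s)
        best = -2.0
        for c in (uniq[:-1] + uniq[1:]) / 2:
            sens = ((s > c) & (y == 1)).sum() / (y == 1).sum()
            spec = ((s <= c) & (y == 0)).sum() / (y == 0).sum()
            best = max(best, sens + spec - 1)
        assert res.j == pytest.approx(best)

    def test_uninformative_score_small_j(self, rng):
        s = rng.normal(size=600)
        y = rng.integers(0, 2, 600)
        res = youden_optimal_cutoff(s, y)
        assert res.j < 0.2

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            youden_optimal_cutoff([1.0, 2.0], [1, 1])


class TestSimpleStats:
    def test_identical_groups_mann_whitney(self):
        x = np.arange(20, dtype=float)
        _, p = mann_whitney_u(x, x.copy())
        assert p > 0.95

    def test_chi_square_hand_value_no_continuity_correction(self):
        chi2, _ = chisquare_independence([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_spearman_perfect_monotone(self, rng):
        x = rng.normal(size=30)
        rho, p = spearman_corr(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 1e-10
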
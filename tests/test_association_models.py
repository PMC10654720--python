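"""Survival and longitudinal model fits: oracles, limits and conventions."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from circfrail import (
    fit_competing_risk, fit_component_models, fit_cox, fit_frailty_lmm,
    fit_ordinal_mixed, metric_correlations, predicted_curves, round_followup,
    sensitivity_suite, simulate_ordinal_trajectories,
    simulate_survival_recovery, simulate_trajectory_recovery,
    standardize_predictor,
)
from circfrail.errors import ConfigurationError, DegenerateSignalError


class TestStandardize:
    def test_unit_sd(self):
        x = pd.Series([3.0, 7.0, 1.0, 9.0, 5.0])
        z, meta = standardize_predictor(x)
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert meta["direction"] == "increase"

    def test_decrease_is_involution(self):
        # flipping the direction twice restores the increase coding
        x = pd.Series(np.random.default_rng(0).normal(5, 2, 50))
        z1, _ = standardize_predictor(x, "decrease")
        z2, _ = standardize_predictor(z1, "decrease")
        zi, _ = standardize_predictor(x, "increase")
        np.testing.assert_allclose(z2, zi, atol=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(DegenerateSignalError):
            standardize_predictor(pd.Series([2.0, 2.0, 2.0]))

    def test_direction_flip_inverts_hr(self):
        df = simulate_survival_recovery(600, 1.5, "decrease", seed=5)
        up = fit_cox(df, "metric", covariates=(), direction="increase")
        dn = fit_cox(df, "metric", covariates=(), direction="decrease")
        assert float(dn["metric"]["estimate"]) == pytest.approx(
            -float(up["metric"]["estimate"]), abs=1e-8
        )


class TestRoundFollowup:
    @pytest.mark.parametrize("t,expected", [(2.4, 2), (2.5, 3), (0.3, 1),
                                            (1.49, 1), (15.8, 16)])
    def test_rounding_rules(self, t, expected):
        assert round_followup([t])[0] == expected

    def test_positive_required(self):
        with pytest.raises(ConfigurationError):
            round_followup([-1.0])


class TestCoxOracle:
    def test_grid_search_partial_likelihood_n10(self):
        """Cox coefficient on a printed 10-row fixture matches a direct
        maximization of the Efron partial likelihood."""
        fixture = pd.DataFrame({
            "metric": [0.8, -1.2, 0.3, 1.5, -0.7, 0.1, 2.0, -0.4, 0.9, -1.6],
            "followup_years": [2.0, 5.0, 3.0, 1.0, 4.0, 2.0, 1.0, 6.0, 3.0, 5.0],
            "frailty_event": [1, 0, 1, 1, 0, 1, 1, 0, 1, 0],
        })
        res = fit_cox(fixture, "metric", covariates=(), round_years=False,
                      min_events=5)
        sd = fixture["metric"].std(ddof=1)
        z = ((fixture["metric"] - fixture["metric"].mean()) / sd).to_numpy()
        T = fixture["followup_years"].to_numpy()
        E = fixture["frailty_event"].to_numpy()

        def efron_nll(beta):
            ll = 0.0
            for t in np.unique(T[E == 1]):
                d_idx = np.flatnonzero((T == t) & (E == 1))
                r_idx = np.flatnonzero(T >= t)
                theta = np.exp(beta * z)
                s_all = theta[r_idx].sum()
                s_tie = theta[d_idx].sum()
                ll += beta * z[d_idx].sum()
                for j in range(len(d_idx)):
                    ll -= np.log(s_all - j / len(d_idx) * s_tie)
            return -ll

        grid = minimize(efron_nll, x0=[0.0])
        assert float(res["metric"]["estimate"]) == pytest.approx(
            float(grid.x[0]), abs=1e-4
        )

    def test_null_simulation_hr_near_one(self):
        hrs = []
        for seed in range(30):
            df = simulate_survival_recovery(500, 1.0, seed=seed)
            res = fit_cox(df, "metric", covariates=())
            hrs.append(np.exp(float(res["metric"]["estimate"])))
        assert np.mean(hrs) == pytest.approx(1.0, abs=0.02)


class TestCompetingRisk:
    @staticmethod
    def _cohort(n, beta, death_rate, seed, death_in_low=0.0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        lam = 0.07 * np.exp(beta * z)
        t_f = rng.exponential(1.0 / lam)
        mu = death_rate * np.exp(-death_in_low * z)
        t_d = (rng.exponential(1.0 / mu) if np.any(mu > 0)
               else np.full(n, np.inf))
        t_c = np.minimum(16.0, rng.exponential(10.0, n))
        obs = np.minimum.reduce([t_f, t_d, t_c])
        ev = np.where(t_f <= np.minimum(t_d, t_c), 1,
                      np.where(t_d <= t_c, 2, 0))
        return pd.DataFrame({"metric": z, "followup_years": np.maximum(obs, 1e-3),
                             "event_type": ev,
                             "frailty_event": (ev == 1).astype(int)})

    def test_matches_cmprsk_style_infinite_risk_cox(self):
        """With administrative-only censoring the subdistribution fit
        equals a Cox fit that keeps deceased subjects at risk forever
        (independent lifelines oracle)."""
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(2)
        n = 250
        z = rng.standard_normal(n)
        t_f = rng.exponential(1.0 / (0.07 * np.exp(0.5 * z)))
        t_d = rng.exponential(1.0 / 0.06, n)
        obs = np.minimum.reduce([t_f, t_d, np.full(n, 10.0)])
        ev = np.where(t_f <= np.minimum(t_d, 10.0), 1,
                      np.where(t_d <= 10.0, 2, 0))
        df = pd.DataFrame({"metric": z, "followup_years": obs,
                           "event_type": ev})
        fg = fit_competing_risk(df, "metric", covariates=(), round_years=False)
        d2 = df.copy()
        d2["z"], _ = standardize_predictor(d2["metric"])
        d2["dur"] = np.where(d2.event_type == 2, 1e6, d2.followup_years)
        d2["ev"] = (d2.event_type == 1).astype(int)
        cph = CoxPHFitter().fit(d2[["z", "dur", "ev"]], "dur", "ev")
        assert float(fg["metric"]["estimate"]) == pytest.approx(
            float(cph.summary.loc["z", "coef"]), abs=5e-3
        )

    def test_no_deaths_reduces_to_cox(self):
        df = self._cohort(400, 0.4, 0.0, seed=3)
        with pytest.warns(UserWarning, match="no competing deaths"):
            fg = fit_competing_risk(df, "metric", covariates=())
        cx = fit_cox(df, "metric", covariates=())
        assert float(fg["metric"]["estimate"]) == pytest.approx(
            float(cx["metric"]["estimate"]), rel=0.05
        )

    def test_null_effect_shr_near_one(self):
        ests = [float(np.exp(fit_competing_risk(
            self._cohort(400, 0.0, 0.05, seed=s), "metric", covariates=()
        )["metric"]["estimate"])) for s in range(12)]
        assert np.mean(ests) == pytest.approx(1.0, abs=0.04)

    def test_mortality_concentrated_in_low_metric_attenuates_shr(self):
        """When deaths hit low-metric subjects first, the subdistribution
        HR for the frailty outcome moves below the cause-specific HR."""
        diffs = []
        for s in range(10):
            # deaths concentrated where the frailty hazard is highest
            df = self._cohort(800, 0.5, 0.15, seed=100 + s, death_in_low=-0.8)
            fg = fit_competing_risk(df, "metric", covariates=())
            cx = fit_cox(df, "metric", covariates=())
            diffs.append(float(cx["metric"]["estimate"])
                         - float(fg["metric"]["estimate"]))
        assert np.mean(diffs) > 0


class TestFrailtyLMM:
    def test_noiseless_linear_trajectories_exact(self):
        long = simulate_trajectory_recovery(
            n=60, seed=1, metric_main=0.0, metric_time=0.0, age_time=0.0,
            rand_intercept_sd=0.0, rand_slope_sd=0.0, residual_sd=0.0,
            slope=0.08, n_years=6,
        )
        res = fit_frailty_lmm(long, "metric")
        assert float(res["time"]["estimate"]) == pytest.approx(0.08, abs=1e-6)

    def test_random_slope_sd_recovered(self):
        ests = []
        for seed in range(6):
            long = simulate_trajectory_recovery(n=400, seed=seed,
                                                rand_slope_sd=0.05, n_years=10)
            res = fit_frailty_lmm(long, "metric")
            fit = res.metadata["fit"]
            cov = fit.cov_re.to_numpy()     # already in data units
            ests.append(np.sqrt(cov[1, 1]))
        assert np.mean(ests) == pytest.approx(0.05, rel=0.2)

    def test_metric_time_interaction_recovered(self):
        ests = []
        for seed in range(8):
            long = simulate_trajectory_recovery(n=500, seed=seed,
                                                metric_time=-0.005)
            res = fit_frailty_lmm(long, "metric", covariates=("age_c",),
                                  direction="decrease")
            ests.append(float(res["metric:time"]["estimate"]))
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.005) < max(2 * mc_se, 5e-4)


class TestComponentModels:
    def test_bmi_slope_recovered_within_2se(self):
        hits, n_rep = 0, 10
        for seed in range(n_rep):
            long = simulate_trajectory_recovery(n=300, seed=seed,
                                                metric_time=-0.01,
                                                residual_sd=0.3)
            long = long.rename(columns={"composite_score": "bmi"})
            res = fit_component_models(long, "metric", "bmi",
                                       direction="decrease")
            est, se = res["metric:time"]["estimate"], res["metric:time"]["se"]
            if abs(est - 0.01) < 2 * se:
                hits += 1
        assert hits >= 8

    def test_fatigue_thresholds_recovered(self):
        ests = []
        for seed in range(6):
            long = simulate_ordinal_trajectories(
                n=250, n_visits=6, thresholds=(0.5, 2.0), beta_time=0.15,
                beta_metric=-0.2, sigma_u=0.8, seed=seed,
            )
            res = fit_component_models(long, "metric", "fatigue")
            ests.append([float(res.terms.loc["threshold_0", "estimate"]),
                         float(res.terms.loc["threshold_1", "estimate"]),
                         float(res["time"]["estimate"])])
        m = np.mean(ests, axis=0)
        mc = np.std(ests, axis=0, ddof=1) / np.sqrt(len(ests))
        assert abs(m[0] - 0.5) < 3 * mc[0] + 0.05
        assert abs(m[1] - 2.0) < 3 * mc[1] + 0.1
        assert abs(m[2] - 0.15) < 3 * mc[2] + 0.02

    def test_null_metric_effect_ci_covers_zero(self):
        long = simulate_trajectory_recovery(n=400, seed=3, metric_time=0.0)
        long = long.rename(columns={"composite_score": "grip_strength"})
        res = fit_component_models(long, "metric", "grip")
        row = res["metric:time"]
        assert row["ci_low"] <= 0.0 <= row["ci_high"]

    def test_missing_fatigue_level_rejected(self):
        long = simulate_ordinal_trajectories(n=60, seed=0)
        long = long[long["fatigue_score"] != 2]
        long["_mt"] = 0.0
        from circfrail.errors import ModelFitError
        with pytest.raises(ModelFitError, match="levels"):
            fit_ordinal_mixed(long, "fatigue_score", ["time"])


class TestSensitivityAndCurves:
    @staticmethod
    def _table(n=600, seed=4):
        df = simulate_survival_recovery(n, 1.4, "decrease", seed=seed)
        rng = np.random.default_rng(seed + 1)
        df["age"] = rng.normal(81, 7, n)
        df["total_activity"] = rng.exponential(200, n)
        df["ad_diagnosis"] = (rng.random(n) < 0.1).astype(int)
        df["pd_diagnosis"] = (rng.random(n) < 0.05).astype(int)
        return df.rename(columns={"metric": "amplitude"})

    def test_age_strata_partition_and_median_split(self):
        table = self._table()
        out = sensitivity_suite(table, "amplitude", covariates=("age",),
                                direction="decrease")
        assert out["age_lt_80"].n + out["age_ge_80"].n == len(table)
        assert out["low_activity"].n in (len(table) // 2, len(table) // 2 + 1)

    def test_null_extra_covariates_barely_move_hr(self):
        table = self._table(n=800, seed=9)
        base = fit_cox(table, "amplitude", covariates=(), direction="decrease")
        adj = sensitivity_suite(
            table, "amplitude", covariates=(), direction="decrease",
            scenarios=("adjust_ad_pd",),
        )["adjust_ad_pd"]
        assert float(adj["amplitude"]["estimate"]) == pytest.approx(
            float(base["amplitude"]["estimate"]), abs=0.05
        )

    def test_cox_curves_ordered_and_degenerate_cases(self):
        table = self._table()
        res = fit_cox(table, "amplitude", covariates=(), direction="decrease")
        curves = predicted_curves(res, table, percentiles=(10, 90))
        lo = curves[curves.percentile == 10].set_index("time")["value"]
        hi = curves[curves.percentile == 90].set_index("time")["value"]
        # harmful-low metric: low-percentile survival lies below high
        assert (lo <= hi + 1e-12).all()
        assert (lo < hi - 1e-6).any()
        with pytest.raises(ConfigurationError):
            predicted_curves(res, table, percentiles=(0, 90))

    def test_lmm_trajectory_curves(self):
        long = simulate_trajectory_recovery(n=300, seed=5, metric_time=-0.005)
        res = fit_frailty_lmm(long, "metric", direction="decrease")
        table = long.groupby("subject_id").first().reset_index()
        curves = predicted_curves(res, table, percentiles=(10, 90))
        assert {"lo", "hi"}.issubset(curves.columns)
        end = curves[curves.time == curves.time.max()]
        low_end = end[end.percentile == 10]["value"].iloc[0]
        high_end = end[end.percentile == 90]["value"].iloc[0]
        assert low_end > high_end   # low metric -> faster frailty rise


class TestCorrelations:
    def test_spearman_matrix_properties(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=80)})
        df["b"] = df["a"] * 2 + rng.normal(size=80) * 0.1
        df["c"] = rng.normal(size=80)
        m = metric_correlations(df)
        assert np.allclose(np.diag(m), 1.0)
        assert m.loc["a", "b"] > 0.9
        assert abs(m.loc["a", "c"]) < 0.35
        assert np.allclose(m, m.T)
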
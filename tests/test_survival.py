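import math

import numpy as np
import pandas as pd
import pytest

from hrvcohort.reference import ReferenceRange
from hrvcohort.survival import (
    AdjustmentSet,
    CoxPH,
    cox_fit,
    cumulative_incidence,
    linear_fit,
    run_model_battery,
    standardize_columns,
)
from hrvcohort.synthetic import CohortGenParams, gen_cohort
from oracles import breslow_loglik_naive, cox_beta_grid_oracle, km_survival_naive


class TestStandardize:
    def test_divides_by_sample_sd(self):
        z, sds = standardize_columns(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(z["a"], [1.0, 2.0, 3.0])
        assert sds["a"] == pytest.approx(2.0)

    def test_unit_sd_column_unchanged(self, rng):
        x = rng.normal(size=100)
        x = x / x.std(ddof=1)
        z, _ = standardize_columns(pd.DataFrame({"a": x}))
        np.testing.assert_allclose(z["a"], x)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="const_col"):
            standardize_columns(pd.DataFrame({"const_col": [1.0, 1.0, 1.0]}))


class TestCox:
    def test_three_subject_closed_form(self):
        # score equation root: u^2 = 1/2, beta = -ln(2)/2
        res = cox_fit(np.array([[1.0], [0.0], [1.0]]), [1, 2, 3], [1, 1, 1])
        assert res.params.iloc[0] == pytest.approx(-0.5 * math.log(2), abs=1e-9)
        assert res.hazard_ratios.iloc[0] == pytest.approx(2 ** -0.5, abs=1e-9)
        assert res.converged

    def test_tiny_datasets_match_grid_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 7))
            x = rng.normal(size=n)
            t = rng.permutation(np.arange(1.0, n + 1))  # distinct times
            e = np.ones(n, dtype=int)
            res = cox_fit(x[:, None], t, e)
            oracle = cox_beta_grid_oracle(x[:, None], t, e)
            assert res.params.iloc[0] == pytest.approx(oracle, abs=2e-4)

    def test_breslow_loglik_matches_naive(self, rng):
        n = 100
        X = rng.normal(size=(n, 2))
        t = rng.exponential(size=n).round(1)  # ties present
        e = rng.integers(0, 2, n)
        e[0] = 1
        model = CoxPH(t, e, X)
        for beta in ([0.0, 0.0], [0.5, -0.3], [-1.0, 2.0]):
            ll, _, _ = model._loglik_score_info(np.asarray(beta))
            assert ll == pytest.approx(
                breslow_loglik_naive(beta, X, t, e), abs=1e-10
            )

    def test_agrees_with_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        X = rng.normal(size=(n, 3))
        t = rng.exponential(np.exp(-0.5 * X[:, 0]))
        e = (rng.random(n) < 0.7).astype(int)
        res = cox_fit(X, t, e)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        ll = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(res.params, ll.params_.values, atol=1e-6)
        np.testing.assert_allclose(res.bse, ll.standard_errors_.values, atol=1e-6)

    def test_per_sd_equivariance(self, rng):
        n = 300
        x = rng.normal(scale=37.0, size=n)
        t = rng.exponential(np.exp(-0.01 * x))
        e = np.ones(n, dtype=int)
        raw = cox_fit(x[:, None], t, e)
        sd = np.std(x, ddof=1)
        std = cox_fit((x / sd)[:, None], t, e)
        assert raw.params.iloc[0] * sd == pytest.approx(std.params.iloc[0], abs=1e-8)

    def test_separation_flagged(self):
        import warnings

        x = np.array([1.0, 1, 1, 0, 0, 0])
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.array([1, 1, 1, 0, 0, 0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cox_fit(x[:, None], t, e)
        assert not res.converged

    def test_summary_table_columns(self):
        res = cox_fit(np.array([[1.0], [0.0], [1.0]]), [1, 2, 3], [1, 1, 1])
        s = res.summary()
        assert {"coef", "hr", "hr_lower", "hr_upper", "p"} <= set(s.columns)
        assert s.loc["x0", "hr_lower"] < s.loc["x0", "hr"] < s.loc["x0", "hr_upper"]


class TestLinear:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = linear_fit(2 * x, x[:, None], names=["x"])
        assert res.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(res.resid, 0.0, atol=1e-10)

    def test_null_covariate_within_three_se(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = linear_fit(y, x[:, None], names=["x"])
        assert abs(res.params["x"]) < 3 * res.bse["x"]

    def test_matches_normal_equations(self, rng):
        n, p = 200, 4
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        res = linear_fit(y, X)
        design = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_collinear_columns_listed(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            linear_fit(rng.normal(size=50), X)


class TestCumulativeIncidence:
    def test_no_events_flat_zero(self):
        curves = cumulative_incidence([1, 2, 3], [0, 0, 0], ["g"] * 3)
        assert np.allclose(curves["g"]["cum_incidence"], 0.0)

    def test_all_deaths_reach_one_with_uniform_steps(self):
        t = [1.0, 2, 3, 4]
        curves = cumulative_incidence(t, [1] * 4, ["g"] * 4)
        ci = curves["g"].set_index("time")["cum_incidence"]
        np.testing.assert_allclose(ci.loc[[1, 2, 3, 4]], [0.25, 0.5, 0.75, 1.0])

    def test_censoring_matches_hand_product_limit(self):
        # 6 subjects: deaths at 2, 5, censored at 1, 3, 4, 6
        t = np.array([2.0, 5.0, 1.0, 3.0, 4.0, 6.0])
        e = np.array([1, 1, 0, 0, 0, 0])
        curves = cumulative_incidence(t, e, ["g"] * 6)
        km = dict(km_survival_naive(t, e))
        ci = curves["g"].set_index("time")["cum_incidence"]
        for et, s in km.items():
            assert ci.loc[et] == pytest.approx(1 - s, abs=1e-12)

    def test_one_minus_km_equals_ecdf_without_censoring(self, rng):
        t = rng.exponential(size=40)
        curves = cumulative_incidence(t, np.ones(40, int), ["g"] * 40)
        ci = curves["g"]
        ecdf = np.searchsorted(np.sort(t), ci["time"], side="right") / 40
        np.testing.assert_allclose(ci["cum_incidence"], ecdf, atol=1e-12)


class TestBattery:
    def _cohort(self, n, coeffs, seed):
        p = CohortGenParams(
            n_subjects=n, healthy_fraction=0.0, log_hr_per_sd=coeffs, seed=seed
        )
        b = gen_cohort(p)
        cohort = b.markers.merge(b.covariates, on="record_id")
        return b, cohort

    def test_recovers_configured_hazard_ratio(self):
        b, cohort = self._cohort(1000, {"dc": math.log(0.70)}, seed=42)
        tbl = run_model_battery(
            b.markers[["record_id", "dc"]], cohort,
            AdjustmentSet("age_sex", ("age", "sex")),
        )
        row = tbl.set_index("marker").loc["dc"]
        assert row["lo"] <= 0.70 <= row["hi"]

    def test_null_marker_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            b, cohort = self._cohort(400, {}, seed=100 + seed)
            tbl = run_model_battery(
                b.markers[["record_id", "sdnn"]], cohort,
                AdjustmentSet("age_sex", ("age", "sex")),
            )
            row = tbl.set_index("marker").loc["sdnn"]
            covered += row["lo"] <= 1.0 <= row["hi"]
        assert covered >= 16  # ~95% nominal coverage

    def test_out_of_range_predictor_doubled_hazard(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.normal(size=n)
        outside = (x < -1.6449) | (x > 1.6449)  # true 5%/95% bounds
        lam = 0.05 * np.where(outside, 2.0, 1.0)
        t_raw = rng.exponential(1 / lam)
        e = (t_raw <= 8).astype(int)
        t = np.minimum(t_raw, 8.0)
        markers = pd.DataFrame({"record_id": np.arange(n).astype(str), "m": x})
        cohort = markers.copy()
        cohort["age"] = rng.normal(65, 10, n)
        cohort["sex"] = rng.integers(0, 2, n)
        cohort["time_all_cause"] = t
        cohort["event_all_cause"] = e
        tbl = run_model_battery(
            markers, cohort, AdjustmentSet("age_sex", ("age", "sex")),
            predictor="out_of_range",
            ranges={"m": ReferenceRange("m", -1.6449, 1.6449)},
        )
        row = tbl.set_index("marker").loc["m"]
        assert row["hr"] == pytest.approx(2.0, rel=0.2)

    def test_adjustment_set_requires_age_sex(self):
        with pytest.raises(ValueError):
            AdjustmentSet("broken", ("age",))
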
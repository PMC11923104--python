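"""Cohort filtering, KM estimation, Cox screens, baseline tables."""

import numpy as np
import pandas as pd
import pytest

from stromaprog.survival import (
    compare_groups,
    cox_multivariate,
    cox_univariate,
    filter_cohort,
    group_baseline_tables,
    km_fit,
)


def make_df(times, events, **cols):
    df = pd.DataFrame({"os_months": times, "event": events})
    for k, v in cols.items():
        df[k] = v
    return df


class TestFilter:
    def test_death_within_30_days_excluded(self):
        df = make_df([0.6, 5.0], [1, 1], os_days=[20, 150])
        out = filter_cohort(df)
        assert len(out) == 1 and out.loc[0, "os_days"] == 150

    def test_censored_early_record_retained(self):
        df = make_df([0.6, 5.0], [0, 1], os_days=[20, 150])
        assert len(filter_cohort(df)) == 2

    def test_months_only_rule(self):
        df = make_df([0.5, 1.5], [1, 1])
        out = filter_cohort(df)
        assert len(out) == 1 and out.loc[0, "os_months"] == 1.5

    def test_clean_cohort_unchanged(self):
        df = make_df([12, 24, 36], [1, 0, 1])
        assert len(filter_cohort(df)) == 3

    def test_all_removed_raises(self):
        with pytest.raises(ValueError):
            filter_cohort(make_df([0.2], [1]))


class TestKaplanMeier:
    def test_single_event(self):
        s = km_fit([5.0], [1])
        assert s.median_os == 5.0
        assert s.km_curve["survival"].iloc[-1] == 0.0

    def test_exponential_median(self, rng):
        lam = 0.05
        t = rng.exponential(1 / lam, 2000)
        s = km_fit(t, np.ones(2000, int))
        assert s.median_os == pytest.approx(np.log(2) / lam, rel=0.10)
        assert s.median_ci[0] < s.median_os < s.median_ci[1]

    def test_textbook_six_patient_worked_set(self):
        # classic product-limit example: deaths at 6,6,6, censored 6+,
        # death 10, censored 11+ -> S(6)=0.5, S(10)=0.5*(1-1/2)=0.25
        times = [6, 6, 6, 6, 10, 11]
        events = [1, 1, 1, 0, 1, 0]
        s = km_fit(times, events)
        curve = dict(zip(s.km_curve["time"], s.km_curve["survival"]))
        assert curve[6.0] == pytest.approx(3 / 6 * 1.0 * 0.0 + 0.5)  # 1 - 3/6
        assert curve[10.0] == pytest.approx(0.5 * (1 - 1 / 2))
        assert s.median_os == 6.0

    def test_median_not_reached(self):
        s = km_fit([5, 6, 7, 8, 9, 10], [1, 0, 0, 0, 0, 0])
        assert not s.median_reached

    def test_survival_nonincreasing(self, rng):
        t = rng.exponential(10, 100)
        e = (rng.random(100) < 0.6).astype(int)
        if e.sum() == 0:
            e[0] = 1
        s = km_fit(t, e)
        assert (np.diff(s.km_curve["survival"]) <= 1e-12).all()


class TestCompareGroups:
    def test_identical_groups_null(self, rng):
        t = np.tile(rng.exponential(20, 100), 2)
        e = np.ones(200, int)
        g = np.repeat([1, 2], 100)
        out = compare_groups(make_df(t, e, g=g), "g")
        assert out["logrank_p"] > 0.9
        assert out["hr_table"]["hr"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_protective_group_hr_recovery(self, rng):
        n = 2000
        g = rng.integers(1, 4, n)
        lam = np.where(g == 1, 0.02, 0.04)
        t = rng.exponential(1 / lam)
        df = make_df(t, np.ones(n, int), g=g)
        out = compare_groups(df, "g")
        hr = out["hr_table"].set_index("variable")
        assert hr.loc["1 vs others", "hr"] == pytest.approx(0.5, abs=0.1)

    def test_ordered_hazards_give_ordered_hrs(self, rng):
        n = 3000
        g = rng.integers(1, 4, n)
        lam = np.select([g == 1, g == 2, g == 3], [0.02, 0.04, 0.08])
        df = make_df(rng.exponential(1 / lam), np.ones(n, int), g=g)
        hr = compare_groups(df, "g")["hr_table"].set_index("variable")
        assert hr.loc["1 vs 3", "hr"] < hr.loc["1 vs 2", "hr"] < 1.0


class TestCox:
    def test_null_variable_small_effect(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        df = make_df(rng.exponential(20, n), np.ones(n, int), x=x)
        res = cox_univariate(df, ["x"]).iloc[0]
        assert abs(np.log(res["hr"])) < 0.1

    def test_binary_rate_doubling_recovers_hr_2(self, rng):
        n = 2000
        x = rng.integers(0, 2, n)
        lam = 0.02 * 2.0**x
        df = make_df(rng.exponential(1 / lam), np.ones(n, int), x=x)
        res = cox_univariate(df, ["x"]).iloc[0]
        assert res["hr"] == pytest.approx(2.0, abs=0.2)

    def test_constant_variable_flagged(self):
        df = make_df([1, 2, 3, 4], [1, 1, 1, 1], x=[1, 1, 1, 1])
        res = cox_univariate(df, ["x"]).iloc[0]
        assert not res["converged"]

    def test_single_variable_multivariate_equals_univariate(self, rng):
        n = 500
        x = rng.integers(0, 2, n)
        lam = 0.02 * 1.8**x
        df = make_df(rng.exponential(1 / lam), np.ones(n, int), x=x)
        uni = cox_univariate(df, ["x"]).iloc[0]
        multi = cox_multivariate(df, ["x"]).iloc[0]
        assert multi["hr"] == pytest.approx(uni["hr"], rel=1e-6)

    def test_joint_recovery_of_independent_effects(self, rng):
        n = 2000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        lam = 0.02 * 0.5**a * 2.0**b
        df = make_df(rng.exponential(1 / lam), np.ones(n, int), a=a, b=b)
        multi = cox_multivariate(df, ["a", "b"]).set_index("variable")
        assert multi.loc["a", "hr"] == pytest.approx(0.5, abs=0.1)
        assert multi.loc["b", "hr"] == pytest.approx(2.0, abs=0.25)
        assert multi.loc["a", "independent_predictor"]

    def test_confounded_copy_attenuated(self, rng):
        n = 2000
        a = rng.standard_normal(n)
        copy = a + 0.3 * rng.standard_normal(n)
        lam = 0.02 * np.exp(0.7 * a)
        df = make_df(rng.exponential(1 / lam), np.ones(n, int), a=a, c=copy)
        uni = cox_univariate(df, ["c"]).set_index("variable")
        multi = cox_multivariate(df, ["a", "c"]).set_index("variable")
        assert abs(np.log(multi.loc["c", "hr"])) < abs(np.log(uni.loc["c", "hr"]))

    def test_collinear_selection_raises(self, rng):
        n = 100
        a = rng.standard_normal(n)
        df = make_df(rng.exponential(20, n), np.ones(n, int), a=a, b=2 * a)
        with pytest.raises(np.linalg.LinAlgError):
            cox_multivariate(df, ["a", "b"])


class TestBaselineTables:
    def test_identical_groups_large_p(self, rng):
        base = rng.normal(60, 8, 100)
        df = pd.DataFrame(
            {"g": np.repeat([0, 1], 100), "age": np.tile(base, 2),
             "os_months": 1.0, "event": 0}
        )
        out = group_baseline_tables(df, "g", ["age"]).iloc[0]
        assert out["p"] > 0.9

    def test_location_shift_detected(self, rng):
        df = pd.DataFrame(
            {
                "g": np.repeat([0, 1], 250),
                "age": np.concatenate(
                    [rng.normal(60, 8, 250), rng.normal(64, 8, 250)]
                ),
                "os_months": 1.0,
                "event": 0,
            }
        )
        out = group_baseline_tables(df, "g", ["age"]).iloc[0]
        assert out["test"] == "mann-whitney"
        assert out["p"] < 0.01

    def test_chi_square_matches_hand_computed_table(self):
        # 2x2 table [[10, 20], [20, 10]]: uncorrected chi2 = 60/9 * 1.5 = 6.66...
        g = np.repeat([0, 1], 30)
        sex = np.array(["F"] * 10 + ["M"] * 20 + ["F"] * 20 + ["M"] * 10)
        df = pd.DataFrame({"g": g, "sex": sex, "os_months": 1.0, "event": 0})
        out = group_baseline_tables(df, "g", ["sex"]).iloc[0]
        # exact-count oracle: chi2 = sum (O-E)^2/E with E = 15 everywhere
        oracle = sum((o - 15) ** 2 / 15 for o in (10, 20, 20, 10))
        assert out["statistic"] == pytest.approx(oracle)

    def test_ordered_categorical_uses_trend_test(self, rng):
        stage = pd.Categorical(
            rng.choice(["I", "II", "III"], 120), ["I", "II", "III"], ordered=True
        )
        df = pd.DataFrame(
            {"g": rng.integers(0, 2, 120), "stage": stage,
             "os_months": 1.0, "event": 0}
        )
        out = group_baseline_tables(df, "g", ["stage"]).iloc[0]
        assert out["test"] == "linear-by-linear"
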
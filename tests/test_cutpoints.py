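"""Cutpoint searches: oracle equivalence, invariances, label algebra."""

import numpy as np
import pytest
from _oracles import (
    logrank_chi2_oracle,
    maxstat_scan_oracle,
    random_survival_cohort,
    standardized_logrank_oracle,
    xtile_scan_oracle,
)

from stromaprog.cutpoints import (
    combined_groups,
    lausen_schumacher_p,
    logrank,
    maxstat_binary,
    merge_sip_lh,
    xtile_two_cut,
)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = np.array([5, 8, 12, 20, 5, 8, 12, 20], float)
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2, p = logrank(times, events, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_risk_tables(self, rng):
        _, times, events = random_survival_cohort(rng, 40)
        labels = rng.integers(0, 2, 40)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        chi2, _ = logrank(times, events, labels)
        assert chi2 == pytest.approx(logrank_chi2_oracle(times, events, labels), rel=1e-6)

    def test_invariant_under_label_permutation(self, rng):
        _, times, events = random_survival_cohort(rng, 30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a, _ = logrank(times, events, labels)
        b, _ = logrank(times, events, 1 - labels)
        assert a == pytest.approx(b)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])


class TestMaxstatBinary:
    def test_forced_separation_recovers_gap(self, rng):
        n = 40
        marker = np.concatenate([rng.uniform(0, 0.015, n // 2),
                                 rng.uniform(0.025, 0.1, n // 2)])
        times = np.concatenate([rng.exponential(5, n // 2),
                                rng.exponential(60, n // 2)]) + 0.1
        events = np.ones(n, int)
        res = maxstat_binary(marker, times, events)
        assert 0.015 <= res.cut_values[0] <= 0.025

    def test_statistic_equals_exhaustive_scan(self, rng):
        for _ in range(5):
            marker, times, events = random_survival_cohort(rng, 60)
            res = maxstat_binary(marker, times, events, 0.1)
            z_best, cut_best = maxstat_scan_oracle(marker, times, events, 0.1)
            assert res.max_statistic == pytest.approx(z_best, rel=1e-9)
            assert res.cut_values[0] == pytest.approx(cut_best)

    def test_monotone_transform_equivariance(self, rng):
        marker, times, events = random_survival_cohort(rng, 80)
        res_lin = maxstat_binary(marker, times, events)
        res_log = maxstat_binary(np.log(marker + 1), times, events)
        np.testing.assert_array_equal(res_lin.group_labels, res_log.group_labels)
        assert res_lin.max_statistic == pytest.approx(res_log.max_statistic)

    def test_permutation_p_agrees_with_approximation_in_order(self, rng):
        marker, times, events = random_survival_cohort(rng, 80)
        res_approx = maxstat_binary(marker, times, events)
        res_perm = maxstat_binary(marker, times, events, permutations=200, seed=1)
        assert res_perm.cut_values == res_approx.cut_values
        # both p-values agree on significance scale (same order of magnitude
        # band): compare on log scale loosely
        assert abs(np.log10(res_perm.p_value + 1e-3)
                   - np.log10(res_approx.p_value + 1e-3)) < 1.0

    def test_lausen_schumacher_monotone_in_b(self):
        ps = [lausen_schumacher_p(b, 0.1, 0.9) for b in (1.0, 2.0, 3.0, 4.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert 0 <= ps[-1] < ps[0] <= 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            maxstat_binary([1, 2, 3], [1, 2, 3], [1, 1, 1])


class TestXtileTwoCut:
    def test_three_strata_recovery(self, rng):
        n = 120
        marker = rng.uniform(0, 1, n)
        lam = np.where(marker < 0.4, 0.1, np.where(marker < 0.7, 0.01, 0.1))
        times = rng.exponential(1 / lam) + 0.01
        events = np.ones(n, int)
        res = xtile_two_cut(marker, times, events)
        c1, c2 = res.cut_values
        assert abs(c1 - 0.4) < 0.08 and abs(c2 - 0.7) < 0.08
        assert set(np.unique(res.group_labels)) == {"low", "intermediate", "high"}

    def test_statistic_equals_double_loop_oracle(self, rng):
        marker, times, events = random_survival_cohort(rng, 60)
        res = xtile_two_cut(marker, times, events, 0.1)
        chi_best, cuts_best = xtile_scan_oracle(marker, times, events, 0.1)
        assert res.max_statistic == pytest.approx(chi_best, rel=1e-6)
        assert res.cut_values == pytest.approx(cuts_best)

    def test_group_size_constraints_respected(self, rng):
        marker, times, events = random_survival_cohort(rng, 100)
        res = xtile_two_cut(marker, times, events, min_group_frac=0.2)
        _, counts = np.unique(res.group_labels, return_counts=True)
        assert counts.min() >= 20

    def test_monotone_transform_equivariance(self, rng):
        marker, times, events = random_survival_cohort(rng, 80)
        a = xtile_two_cut(marker, times, events)
        b = xtile_two_cut(marker**3, times, events)  # strictly increasing
        np.testing.assert_array_equal(a.group_labels, b.group_labels)
        assert a.max_statistic == pytest.approx(b.max_statistic)


class TestLabelAlgebra:
    def test_merge_sip_lh(self):
        out = merge_sip_lh(["low", "intermediate", "high"])
        np.testing.assert_array_equal(out, ["LH", "intermediate", "LH"])

    def test_merge_preserves_all_intermediate(self):
        out = merge_sip_lh(["intermediate"] * 4)
        assert (out == "intermediate").all()

    def test_merge_conserves_counts(self, rng):
        labels = rng.choice(["low", "intermediate", "high"], 100)
        merged = merge_sip_lh(labels)
        assert (merged == "LH").sum() == np.isin(labels, ["low", "high"]).sum()

    def test_merge_rejects_unknown(self):
        with pytest.raises(ValueError):
            merge_sip_lh(["low", "mid"])

    @pytest.mark.parametrize(
        "sip,lip,expected",
        [
            ("intermediate", "high", 1),
            ("LH", "low", 3),
            ("intermediate", "low", 2),
            ("LH", "high", 2),
        ],
    )
    def test_combined_group_definitions(self, sip, lip, expected):
        assert combined_groups([sip], [lip])[0] == expected

    def test_combined_groups_reject_missing(self):
        with pytest.raises(ValueError):
            combined_groups(["intermediate"], ["maybe"])
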
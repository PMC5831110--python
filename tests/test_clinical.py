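"""Clinical statistics: cohort summaries, rank tests, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexmeta as cm
from coexmeta.clinical import (KMCurve, dichotomize_expression, km_estimator,
                               kruskal_wallis, logrank_hr, percent,
                               summarize_cohort, survival_by_group)


def _cohort_with_coo(n_abc=592, n_gcb=830, n_unc=260, total=1804):
    coo = (["ABC"] * n_abc + ["GCB"] * n_gcb + ["unclassified"] * n_unc
           + [None] * (total - n_abc - n_gcb - n_unc))
    return pd.DataFrame({"sample_id": [f"s{i}" for i in range(total)],
                         "time": 1.0, "event": 0, "coo": coo})


class TestSummarizeCohort:
    def test_subtype_shares_match_printed_percentages(self):
        out = summarize_cohort(_cohort_with_coo(), fields=("coo",))
        out = out.set_index("level")
        assert out.loc["ABC", "pct"] == 35.2
        assert out.loc["GCB", "pct"] == 49.3
        assert out.loc["unclassified", "pct"] == 15.5
        assert out.loc["ABC", "pct_int"] == 35
        assert out.loc["GCB", "pct_int"] == 49
        assert out.loc["unclassified", "pct_int"] == 15

    def test_availability_fraction(self):
        out = summarize_cohort(_cohort_with_coo(), fields=("coo",))
        avail = out[out["level"] == "<available>"].iloc[0]
        assert avail["n"] == 1682
        assert avail["pct"] == 93.2
        assert avail["pct_int"] == 93

    def test_empty_table(self):
        out = summarize_cohort(pd.DataFrame(columns=["coo"]), fields=("coo",))
        assert out["n"].tolist() == [0]
        assert out["pct"].tolist() == [0.0]

    def test_level_percentages_sum_to_hundred(self):
        out = summarize_cohort(_cohort_with_coo(), fields=("coo",))
        levels = out[out["level"] != "<available>"]
        assert levels["pct"].sum() == pytest.approx(100.0, abs=0.2)

    def test_round_half_up(self):
        assert percent(1, 8) == 12.5
        assert percent(1, 8, 0) == 13  # 12.5 rounds up, not to even


class TestKruskalWallis:
    def test_hand_computed_h(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                              ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_identical_groups_give_zero(self):
        h, _ = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(300):
            vals = rng.normal(size=30)
            labels = np.repeat(["a", "b", "c"], 10)
            ps.append(kruskal_wallis(vals, labels)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDichotomize:
    def test_median_split(self):
        np.testing.assert_array_equal(
            dichotomize_expression([1, 2, 3, 4]),
            ["low", "low", "high", "high"])

    def test_tertile_top(self):
        labels = dichotomize_expression(range(1, 10), rule="tertile-top")
        assert list(labels[-3:]) == ["high"] * 3
        assert list(labels[:6]) == ["low"] * 6

    def test_median_ties_assigned_low(self):
        labels = dichotomize_expression([1, 2, 2, 3])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize_expression([5.0, 5.0, 5.0])


class TestKMEstimator:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimator([3, 5, 7], [0, 0, 0])
        assert curve.at(7) == 1.0

    def test_product_limit_by_hand(self):
        curve = km_estimator([1, 2], [1, 1])
        assert curve.at(1) == pytest.approx(0.5)
        assert curve.at(2) == pytest.approx(0.0)

    def test_single_censored_subject(self):
        curve = km_estimator([4.0], [0])
        assert curve.at(0) == 1.0 and curve.at(4.0) == 1.0

    def test_monotone_nonincreasing_from_one(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, size=50)
        curve = km_estimator(t, e)
        assert curve.at(0) == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([-1.0], [1])


def _brute_oe(t1, e1, t2, e2):
    """Per-event-time 2x2 risk-set oracle, written independently."""
    all_events = sorted({t for t, e in zip(list(t1) + list(t2),
                                           list(e1) + list(e2)) if e == 1})
    E1 = 0.0
    for t in all_events:
        n1 = sum(1 for x in t1 if x >= t)
        n2 = sum(1 for x in t2 if x >= t)
        d = (sum(1 for x, e in zip(t1, e1) if x == t and e == 1)
             + sum(1 for x, e in zip(t2, e2) if x == t and e == 1))
        E1 += d * n1 / (n1 + n2)
    return E1


class TestLogrankHR:
    def test_identical_groups(self):
        t = [1, 2, 3, 4.0]
        e = [1, 1, 0, 1]
        out = logrank_hr(t, e, t, e)
        assert out.hazard_ratio == pytest.approx(1.0)
        assert out.chi_square == pytest.approx(0.0, abs=1e-12)
        assert out.ci_low < 1.0 < out.ci_high

    def test_four_patient_worked_example(self):
        t1, e1 = [1.0, 2.0], [1, 1]
        t2, e2 = [3.0, 4.0], [1, 1]
        out = logrank_hr(t1, e1, t2, e2)
        assert out.expected[0] == pytest.approx(_brute_oe(t1, e1, t2, e2))
        assert out.observed == (2.0, 2.0)
        # all observed/expected mass accounted for
        assert sum(out.expected) == pytest.approx(4.0)

    def test_randomized_tables_match_brute_force_and_lifelines(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(11)
        for _ in range(30):
            n1, n2 = rng.integers(3, 12, size=2)
            t1 = rng.integers(1, 8, size=n1).astype(float)
            t2 = rng.integers(1, 8, size=n2).astype(float)
            e1 = rng.integers(0, 2, size=n1)
            e2 = rng.integers(0, 2, size=n2)
            if e1.sum() == 0 or e2.sum() == 0:
                continue
            out = logrank_hr(t1, e1, t2, e2)
            assert out.expected[0] == pytest.approx(_brute_oe(t1, e1, t2, e2),
                                                    abs=1e-10)
            ll = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
            assert out.chi_square == pytest.approx(ll.test_statistic, abs=1e-8)
            assert out.p == pytest.approx(ll.p_value, abs=1e-8)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(13)
        t1 = rng.exponential(5, 40)
        t2 = rng.exponential(10, 40)
        e1 = np.ones(40, int)
        e2 = np.ones(40, int)
        a = logrank_hr(t1, e1, t2, e2)
        b = logrank_hr(t2, e2, t1, e1)
        assert a.hazard_ratio == pytest.approx(1 / b.hazard_ratio)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_hr([1.0], [0], [2.0], [0])


class TestSurvivalByGroup:
    def test_strata_cover_arm_by_coo(self):
        cfg = cm.ClinicalSimConfig(baseline_hazard=0.05, rng_seed=6,
                                   log_hazard_effects={"high": np.log(2)})
        groups = {f"s{i}": ("high" if i % 2 else "low") for i in range(600)}
        clin = cm.generate_clinical(cfg, groups)
        out = survival_by_group(clin)
        assert {"HR", "p", "arm", "coo"} <= set(out.columns)
        assert (out["HR"] > 0).all()
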
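"""Estimators and paired tests: Jeffreys/Wilson, group metrics, McNemar,
generalized score comparison of predictive values, reporting."""
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hs

from helpers import make_cohort
from myotriage.metrics import (
    build_confusion,
    compare_accuracy,
    compare_predictive_values,
    fmt_percent,
    group_metrics,
    jeffreys_proportion,
    mcnemar_paired,
    paired_pv_score_test,
    performance_report,
    wilson_interval,
)
from myotriage.models import CMYC_01H, TriageConfusion, ValidationError
from myotriage.triage import classify_cohort


class TestJeffreys:
    @pytest.mark.parametrize(
        "x,n,expected_pct,decimals",
        [(346, 347, 99.57, 2), (87, 122, 71.14, 2), (324, 325, 99.5, 1)],
    )
    def test_posterior_mean_matches_published_rounding(self, x, n, expected_pct, decimals):
        est = jeffreys_proportion(x, n)
        assert round(100 * est.value, decimals) == expected_pct

    def test_empty_group_returns_flagged_prior_mean(self):
        est = jeffreys_proportion(0, 0)
        assert est.value == 0.5
        assert est.degenerate
        assert (est.lower, est.upper) == (0.0, 1.0)

    def test_equal_tailed_interval_equals_beta_quantiles(self):
        est = jeffreys_proportion(5, 10, conf=0.95)
        lo, hi = st.beta.ppf([0.025, 0.975], 5.5, 5.5)
        assert est.lower == pytest.approx(lo)
        assert est.upper == pytest.approx(hi)

    def test_hpd_interval_matches_published_style_bounds(self):
        # J-shaped posterior: one-sided interval reaching 1
        est = jeffreys_proportion(346, 347, interval="hpd")
        assert round(100 * est.lower, 2) == 98.88
        assert round(100 * est.upper, 2) == 100.0
        est = jeffreys_proportion(87, 122, interval="hpd")
        assert round(100 * est.lower, 1) == 63.1
        assert round(100 * est.upper, 2) == 78.99

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(n=hs.integers(min_value=2, max_value=500), data=hs.data())
    def test_point_estimate_shrinks_towards_half(self, n, data):
        x = data.draw(hs.integers(min_value=1, max_value=n - 1))
        est = jeffreys_proportion(x, n)
        raw = x / n
        assert min(raw, 0.5) <= est.value <= max(raw, 0.5)
        if raw != 0.5:
            assert abs(est.value - 0.5) < abs(raw - 0.5)
        assert est.lower <= est.value <= est.upper


class TestWilson:
    def test_boundary_counts_touch_zero_and_one(self):
        assert wilson_interval(0, 10)[0] == 0.0
        assert wilson_interval(10, 10)[1] == 1.0

    def test_closed_form_oracle(self):
        lo, hi = wilson_interval(5, 10, conf=0.95)
        assert lo == pytest.approx(0.2366, abs=5e-4)
        assert hi == pytest.approx(0.7634, abs=5e-4)

    def test_zero_n_rejected(self):
        with pytest.raises(ValidationError):
            wilson_interval(0, 0)

    def test_interval_contains_proportion_and_tightens_with_n(self):
        for x, n in [(3, 10), (30, 100), (300, 1000)]:
            lo, hi = wilson_interval(x, n)
            assert lo <= x / n <= hi
        widths = [
            np.diff(wilson_interval(3 * k, 10 * k))[0] for k in (1, 10, 100)
        ]
        assert widths[0] > widths[1] > widths[2]


class TestGroupMetrics:
    def test_perfect_classifier(self):
        conf = TriageConfusion(0, 50, 0, 0, 20, 0)
        m = group_metrics(conf)
        assert m["sensitivity"].value == 1.0
        assert m["specificity"].value == 1.0
        assert m["lr_minus"].value == 0.0
        assert math.isinf(m["lr_plus"].value)

    def test_published_style_table_reproduces_observe_prevalence(self):
        conf = TriageConfusion(
            ruleout_pos=1, ruleout_neg=346, observe_pos=26, observe_neg=168,
            rulein_pos=87, rulein_neg=35,
        )
        m = group_metrics(conf)
        assert m["observe_prevalence"].value == pytest.approx(26 / 194)
        assert fmt_percent(26, 194) == "13.4%"
        assert round(100 * m["npv"].value, 2) == 99.57
        assert round(100 * m["ppv"].value, 2) == 71.14
        assert m["sensitivity"].value == pytest.approx(113 / 114)

    def test_empty_groups_reported_undefined_not_zero(self):
        conf = TriageConfusion(0, 0, 10, 50, 0, 0)
        m = group_metrics(conf)
        assert not m["npv"].defined and math.isnan(m["npv"].value)
        assert not m["ppv"].defined
        assert m["efficacy"].value == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        counts=hs.lists(hs.integers(min_value=0, max_value=200), min_size=6, max_size=6)
    )
    def test_likelihood_ratio_identities(self, counts):
        conf = TriageConfusion(*counts)
        m = group_metrics(conf)
        sens, spec = m["sensitivity"], m["specificity"]
        if not (sens.defined and spec.defined) or spec.value in (0.0, 1.0):
            return
        assert m["lr_plus"].value * (1 - spec.value) == pytest.approx(sens.value)
        assert m["lr_minus"].value * spec.value == pytest.approx(1 - sens.value)


class TestMcNemar:
    def test_symmetric_discordance_gives_zero(self):
        a = np.array([True] * 5 + [False] * 5)
        b = np.array([False] * 5 + [True] * 5)
        assert mcnemar_paired(a, b).statistic == 0.0

    def test_b6_c2_oracle(self):
        a = np.array([True] * 6 + [False] * 2 + [True] * 10)
        b = np.array([False] * 6 + [True] * 2 + [True] * 10)
        res = mcnemar_paired(a, b)
        assert res.statistic == pytest.approx(2.0)
        assert res.pvalue == pytest.approx(st.chi2.sf(2.0, 1), abs=1e-9)
        assert res.pvalue == pytest.approx(0.1573, abs=5e-4)

    def test_no_discordance_is_degenerate(self):
        a = np.array([True, False, True])
        res = mcnemar_paired(a, a)
        assert (res.statistic, res.pvalue) == (0.0, 1.0)
        assert res.degenerate

    def test_statistic_invariant_to_swapping_algorithms(self):
        rng = np.random.default_rng(3)
        a = rng.random(100) < 0.7
        b = rng.random(100) < 0.7
        assert mcnemar_paired(a, b).statistic == mcnemar_paired(b, a).statistic


def tables_from_specs(cohort, spec_a, spec_b):
    return classify_cohort(cohort, spec_a), classify_cohort(cohort, spec_b)


class TestPairedPredictiveValues:
    def test_identical_outputs_degenerate(self, cohort_small):
        t = classify_cohort(cohort_small, CMYC_01H)
        res = compare_predictive_values(t, t.copy(), which="npv")
        assert res.statistic == 0.0 and res.pvalue == 1.0 and res.degenerate

    def test_sign_follows_difference(self):
        # A's rule-out group is cleaner than B's
        z, p = paired_pv_score_test(50, 1, 20, 0, 5, 6)
        assert z > 0 and p < 0.05

    def test_empty_group_raises_with_bootstrap_advice(self, cohort_small):
        t = classify_cohort(cohort_small, CMYC_01H)
        t2 = t.copy()
        t2.loc[t2["category"] == "rule_in", "category"] = "observe"
        with pytest.raises(ValidationError, match="bootstrap"):
            compare_predictive_values(t, t2, which="ppv")

    def test_pvalue_agrees_with_percentile_bootstrap_oracle(self):
        """Fixed 40-patient paired dataset; score p within 0.02 of a 10^4
        replicate percentile-bootstrap p for the NPV difference."""
        # cells (in-both, A-only, B-only, neither) x (healthy, diseased)
        cells = {  # healthy counts, diseased counts
            "both": (10, 2),
            "a_only": (8, 1),
            "b_only": (3, 3),
            "neither": (8, 5),
        }
        rows = []
        for (cat_a, cat_b), key in [
            (("rule_out", "rule_out"), "both"),
            (("rule_out", "observe"), "a_only"),
            (("observe", "rule_out"), "b_only"),
            (("observe", "observe"), "neither"),
        ]:
            healthy, diseased = cells[key]
            for label, count in ((0, healthy), (1, diseased)):
                for _ in range(count):
                    rows.append((cat_a, cat_b, label))
        ids = [f"p{i}" for i in range(len(rows))]
        ta = pd.DataFrame(
            {"id": ids, "category": [r[0] for r in rows], "basis": "0/1h",
             "fired_criterion": "", "nstemi": [r[2] for r in rows]}
        )
        tb = ta.copy()
        tb["category"] = [r[1] for r in rows]
        res = compare_predictive_values(ta, tb, which="npv")

        # independent oracle: percentile bootstrap over the 8 patient cells
        rng = np.random.default_rng(0)
        probs = np.array([10, 2, 8, 1, 3, 3, 8, 5]) / 40
        draws = rng.multinomial(40, probs, size=10_000)
        sb, fb, sa, fa, s_b, f_b, _, _ = draws.T
        n1 = sb + fb + sa + fa
        n2 = sb + fb + s_b + f_b
        ok = (n1 > 0) & (n2 > 0)
        d = (sb + sa)[ok] / n1[ok] - (sb + s_b)[ok] / n2[ok]
        p_boot = 2 * min((d <= 0).mean(), (d >= 0).mean())
        assert res.pvalue == pytest.approx(p_boot, abs=0.02)

    def test_detects_a_two_point_npv_gap_at_n_2000(self):
        """Power smoke test: true NPV gap ~2 points, 500 paired replicates."""
        rng = np.random.default_rng(42)
        prev, spc, sens_a, sens_b = 0.2, 0.6, 0.95, 0.90
        # conditionally independent tests; cells of the rule-out (negative)
        # 2x2 split by disease
        p_cells = [
            (1 - prev) * spc * spc,          # healthy, both negative
            prev * (1 - sens_a) * (1 - sens_b),
            (1 - prev) * spc * (1 - spc),    # healthy, A-only negative
            prev * (1 - sens_a) * sens_b,
            (1 - prev) * (1 - spc) * spc,    # healthy, B-only negative
            prev * sens_a * (1 - sens_b),
        ]
        p_cells.append(1.0 - sum(p_cells))
        draws = rng.multinomial(2000, p_cells, size=500)
        z, p = paired_pv_score_test(*[draws[:, i] for i in range(6)])
        assert (np.asarray(p) < 0.05).mean() > 0.5


class TestPerformanceReport:
    @pytest.fixture()
    def toy_cohort(self):
        return make_cohort(
            [
                {"cmyc_0h": 5.0, "cmyc_1h": 5.0, "nstemi": 0},
                {"cmyc_0h": 8.0, "cmyc_1h": 9.0, "nstemi": 0},
                {"cmyc_0h": 150.0, "cmyc_1h": 160.0, "nstemi": 1},
                {"cmyc_0h": 200.0, "cmyc_1h": 210.0, "nstemi": 0},
                {"cmyc_0h": 50.0, "cmyc_1h": 52.0, "nstemi": 1},
                {"cmyc_0h": 30.0, "cmyc_1h": 30.0, "nstemi": 0},
            ]
        )

    def test_toy_report_matches_hand_computation(self, toy_cohort):
        table = classify_cohort(toy_cohort, CMYC_01H)
        report = performance_report({"cmyc": table})
        entry = report["algorithms"]["cmyc"]
        assert entry["counts"] == {
            "rule_out": 2, "rule_in": 2, "observe": 2, "indeterminate": 0,
            "rule_out_0h": 2, "rule_in_0h": 2, "efficacy": 4, "efficacy_0h": 4,
        }
        m = entry["metrics"]
        assert m["sensitivity"]["value"] == 1.0  # no positives ruled out
        assert m["specificity"]["value"] == pytest.approx(3 / 4)
        assert m["npv"]["value"] == pytest.approx(2.5 / 3)
        assert m["ppv"]["value"] == pytest.approx(1.5 / 3)
        assert m["efficacy"]["value"] == pytest.approx(4 / 6)

    def test_proportions_partition_and_counts_match_classification(self, cohort_small):
        table = classify_cohort(cohort_small, CMYC_01H)
        report = performance_report({"cmyc": table})
        counts = report["algorithms"]["cmyc"]["counts"]
        assert (
            counts["rule_out"] + counts["rule_in"] + counts["observe"]
            + counts["indeterminate"]
            == report["n"]
            == len(cohort_small)
        )
        assert counts["rule_out"] == (table["category"] == "rule_out").sum()

    def test_pairwise_comparison_block_present(self, cohort_small):
        ta = classify_cohort(cohort_small, CMYC_01H)
        from test_triage import ESC_TNT

        tb = classify_cohort(cohort_small, ESC_TNT)
        report = performance_report({"cmyc": ta, "tnt": tb})
        comp = report["comparisons"]["cmyc_vs_tnt"]
        for key in ("p_sensitivity", "p_specificity", "p_npv", "p_ppv", "p_ruleout"):
            assert "pvalue" in comp[key] or "error" in comp[key]

    def test_mismatched_cohorts_listed(self, cohort_small):
        ta = classify_cohort(cohort_small, CMYC_01H)
        tb = ta.iloc[:-5].copy()
        with pytest.raises(ValidationError, match="unmatched"):
            compare_accuracy(ta, tb)
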
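"""Triage engine: criterion order, boundaries, conventions, dual marker."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hs

from helpers import make_cohort
from myotriage.models import (
    AlgorithmSpec,
    CMYC_01H,
    DecisionBasis,
    PatientRecord,
    TriageCategory,
    ValidationError,
)
from myotriage.triage import (
    TriageInputError,
    classify_arrays,
    classify_cohort,
    classify_patient,
    dual_marker_classify,
)

ESC_TNT = AlgorithmSpec(
    name="esc-tnt",
    marker="tnt",
    ruleout_single_0h=5.0,
    ruleout_paired_0h=12.0,
    ruleout_paired_delta=3.0,
    rulein_0h=52.0,
    rulein_delta=5.0,
    delta_convention="unsigned",
    ruleout_single_requires_onset_gt=3.0,
)

NEUTRAL_BOOSTER = AlgorithmSpec(
    name="neutral",
    marker="cmyc",
    ruleout_single_0h=0.0,
    ruleout_paired_0h=0.0,
    ruleout_paired_delta=0.0,
    rulein_0h=float("inf"),
    rulein_delta=float("inf"),
)


def rec(c0, c1=None, onset=1.0, marker="cmyc", **extra):
    c0d = {marker: c0}
    c1d = {} if c1 is None else {marker: c1}
    return PatientRecord(id="x", c0=c0d, c1=c1d, onset_hours=onset, **extra)


class TestCmycRuleSet:
    @pytest.mark.parametrize(
        "c0,c1,category,basis,criterion",
        [
            # single-sample rule-out fires irrespective of onset, without 1 h
            (8, None, "rule_out", "0h", "RULE_OUT_SINGLE_0H"),
            # direct rule-in at presentation
            (150, None, "rule_in", "0h", "RULE_IN_0H"),
            # signed fall below the paired delta threshold rules out
            (17, 12, "rule_out", "0/1h", "RULE_OUT_PAIRED"),
            # nothing fires: observe
            (20, 22, "observe", "0/1h", "OBSERVE"),
            # single-sample rule-out precedes the delta rule-in branch
            (9, 25, "rule_out", "0h", "RULE_OUT_SINGLE_0H"),
            # delta rule-in when 0 h steps pass over
            (20, 40, "rule_in", "0/1h", "RULE_IN_DELTA"),
        ],
    )
    def test_classification_traces_the_stated_order(
        self, c0, c1, category, basis, criterion
    ):
        res = classify_patient(rec(c0, c1, onset=1.0), CMYC_01H)
        assert res.category.value == category
        assert res.basis.value == basis
        assert res.fired_criterion == criterion

    @pytest.mark.parametrize(
        "c0,c1,category",
        [
            (10, 15, "observe"),  # single rule-out is strict "below" 10
            (9.99, 15, "rule_out"),  # just under the cut-off rules out
            (140, None, "rule_in"),  # rule-in is inclusive "at least"
        ],
    )
    def test_boundary_semantics(self, c0, c1, category):
        assert classify_patient(rec(c0, c1), CMYC_01H).category.value == category

    def test_paired_ruleout_boundary_delta_is_strict(self):
        # delta exactly 4 does not rule out; 3.9 does
        assert classify_patient(rec(10, 14), CMYC_01H).category.value == "observe"
        assert classify_patient(rec(10, 13.9), CMYC_01H).category.value == "rule_out"


class TestMissingData:
    def test_missing_1h_without_0h_resolution_is_indeterminate(self):
        res = classify_patient(rec(50, None), CMYC_01H)
        assert res.category is TriageCategory.INDETERMINATE
        assert res.fired_criterion == "NO_1H_SAMPLE"

    def test_missing_0h_value_errors(self):
        with pytest.raises(TriageInputError, match="0 h"):
            classify_patient(PatientRecord(id="x", c0={}), CMYC_01H)

    def test_negative_concentration_errors(self):
        with pytest.raises(ValidationError, match="negative"):
            classify_patient(rec(-1.0), CMYC_01H)

    def test_onset_gate_needs_onset(self):
        with pytest.raises(TriageInputError, match="onset"):
            classify_patient(rec(4, 5, onset=None, marker="tnt"), ESC_TNT)


class TestOnsetGate:
    def test_early_presenter_blocked_from_single_sample_ruleout(self):
        res = classify_patient(rec(4, 4, onset=2.0, marker="tnt"), ESC_TNT)
        # falls through to the paired branch instead
        assert res.fired_criterion == "RULE_OUT_PAIRED"
        assert res.basis is DecisionBasis.ZERO_ONE_H

    def test_late_presenter_uses_single_sample_ruleout(self):
        res = classify_patient(rec(4, 4, onset=4.0, marker="tnt"), ESC_TNT)
        assert res.fired_criterion == "RULE_OUT_SINGLE_0H"
        assert res.basis is DecisionBasis.ZERO_H_ONLY


class TestDeltaConventions:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        c0=hs.floats(min_value=5.0, max_value=60.0),
        d=hs.floats(min_value=0.0, max_value=30.0),
    )
    def test_unsigned_rule_blind_to_rise_vs_fall(self, c0, d):
        d = min(d, c0)  # keep c1 non-negative
        rise = classify_patient(rec(c0, c0 + d, onset=4.0, marker="tnt"), ESC_TNT)
        fall = classify_patient(rec(c0, c0 - d, onset=4.0, marker="tnt"), ESC_TNT)
        assert rise.category == fall.category

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        c0=hs.floats(min_value=0.0, max_value=139.0),
        c1=hs.floats(min_value=0.0, max_value=400.0),
    )
    def test_signed_rule_never_rules_in_on_a_fall(self, c0, c1):
        res = classify_patient(rec(c0, c1), CMYC_01H)
        if res.fired_criterion == "RULE_IN_DELTA":
            assert c1 > c0


class TestCohortClassification:
    def test_three_forced_records_partition_one_each(self):
        cohort = make_cohort(
            [
                {"cmyc_0h": 5.0, "cmyc_1h": 5.0},
                {"cmyc_0h": 20.0, "cmyc_1h": 22.0},
                {"cmyc_0h": 200.0, "cmyc_1h": 210.0},
            ]
        )
        table = classify_cohort(cohort, CMYC_01H)
        counts = table["category"].value_counts()
        assert counts["rule_out"] == counts["observe"] == counts["rule_in"] == 1

    def test_counts_partition_the_cohort(self, cohort_10k):
        table = classify_cohort(cohort_10k, CMYC_01H)
        assert len(table) == len(cohort_10k)
        assert table["category"].value_counts().sum() == len(cohort_10k)

    def test_default_cohort_ruleout_fraction_near_published(self, cohort_10k):
        """Simulation sanity check: rule-out within +-5 points of 52.3%."""
        table = classify_cohort(cohort_10k, CMYC_01H)
        frac = 100.0 * (table["category"] == "rule_out").mean()
        assert abs(frac - 52.3) <= 5.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            classify_cohort(pd.DataFrame(columns=["id", "cmyc_0h"]), CMYC_01H)

    def test_error_carries_patient_id(self):
        cohort = make_cohort([{"cmyc_0h": -3.0, "cmyc_1h": 5.0, "id": "BAD01"}])
        with pytest.raises(ValidationError, match="BAD01"):
            classify_cohort(cohort, CMYC_01H)


class TestVectorisedEquivalence:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        c0=hs.floats(min_value=0.0, max_value=300.0),
        delta=hs.floats(min_value=-50.0, max_value=80.0),
        missing=hs.booleans(),
        onset=hs.floats(min_value=0.1, max_value=12.0),
        spec_idx=hs.integers(min_value=0, max_value=1),
    )
    def test_array_path_matches_record_path(self, c0, delta, missing, onset, spec_idx):
        spec = (CMYC_01H, ESC_TNT)[spec_idx]
        c1 = max(c0 + delta, 0.0)
        record = rec(c0, None if missing else c1, onset=onset, marker=spec.marker)
        expected = classify_patient(record, spec)
        cat, basis = classify_arrays(
            np.array([c0]),
            np.array([np.nan if missing else c1]),
            np.array([onset]),
            spec,
        )
        codes = ["rule_out", "observe", "rule_in", "indeterminate"]
        assert codes[cat[0]] == expected.category.value
        assert ["0h", "0/1h"][basis[0]] == expected.basis.value


class TestDualMarker:
    def test_booster_rules_out_low_cmyc_despite_high_troponin_early(self):
        record = PatientRecord(
            id="x", c0={"cmyc": 8.0, "tnt": 20.0}, c1={"tnt": 21.0}, onset_hours=2.0
        )
        res = dual_marker_classify(record, ESC_TNT, CMYC_01H)
        assert res.category is TriageCategory.RULE_OUT
        assert res.basis is DecisionBasis.ZERO_H_ONLY
        assert res.fired_criterion == "BOOSTER_RULE_OUT_SINGLE_0H"

    def test_booster_rules_in_high_cmyc_regardless_of_troponin(self):
        record = PatientRecord(
            id="x", c0={"cmyc": 150.0, "tnt": 7.0}, c1={"tnt": 7.0}, onset_hours=5.0
        )
        res = dual_marker_classify(record, ESC_TNT, CMYC_01H)
        assert res.category is TriageCategory.RULE_IN
        assert res.fired_criterion == "BOOSTER_RULE_IN_0H"

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        cmyc=hs.floats(min_value=0.0, max_value=400.0),
        tnt=hs.floats(min_value=0.0, max_value=120.0),
        dt=hs.floats(min_value=-10.0, max_value=20.0),
        onset=hs.floats(min_value=0.1, max_value=12.0),
    )
    def test_neutral_booster_is_identity(self, cmyc, tnt, dt, onset):
        record = PatientRecord(
            id="x",
            c0={"cmyc": cmyc, "tnt": tnt},
            c1={"tnt": max(tnt + dt, 0.0)},
            onset_hours=onset,
        )
        plain = classify_patient(record, ESC_TNT)
        boosted = dual_marker_classify(record, ESC_TNT, NEUTRAL_BOOSTER)
        assert plain == boosted


class TestThresholdMonotonicity:
    def test_raising_ruleout_and_rulein_thresholds_moves_counts_one_way(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = 200
            c0 = np.exp(rng.normal(2.8, 1.2, n))
            c1 = np.maximum(c0 + rng.normal(0, 8, n), 0.0)
            a = rng.uniform(2, 20)
            b = rng.uniform(a, 30)
            spec1 = AlgorithmSpec("s1", "cmyc", a, b, 4.0, 140.0, 15.0)
            spec2 = AlgorithmSpec("s2", "cmyc", min(a * 1.5, b), b, 4.0, 140.0, 15.0)
            spec3 = AlgorithmSpec("s3", "cmyc", a, b, 4.0, 200.0, 15.0)
            cats1, _ = classify_arrays(c0, c1, None, spec1)
            cats2, _ = classify_arrays(c0, c1, None, spec2)
            cats3, _ = classify_arrays(c0, c1, None, spec3)
            assert (cats2 == 0).sum() >= (cats1 == 0).sum()
            assert (cats3 == 2).sum() <= (cats1 == 2).sum()
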
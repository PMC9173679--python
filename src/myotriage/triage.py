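"""Apply 0/1h triage rule sets to patient records.

A rule set (:class:`~myotriage.models.AlgorithmSpec`) is evaluated in a
fixed criterion order:

1. rule-in on the 0 h sample (``c0 >= rulein_0h``);
2. single-sample rule-out (``c0 < ruleout_single_0h``, subject to the
   onset gate when configured);
3. rule-in on the 0/1 h change (``delta >= rulein_delta``);
4. paired rule-out (``c0 < ruleout_paired_0h`` and
   ``delta < ruleout_paired_delta``);
5. otherwise observe.

Steps 1–2 use the presentation sample only; a patient resolved there never
consults the delta.  If the 1 h sample is missing and steps 1–2 did not
fire, the patient is INDETERMINATE (not observe), so that efficacy
denominators stay explicit.  The order is configurable via ``precedence``
(0 h steps always precede delta steps of the same direction in the default).
"""
from __future__ import annotations

import logging
import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    AlgorithmSpec,
    DecisionBasis,
    PatientRecord,
    TriageCategory,
    TriageResult,
    ValidationError,
)

__all__ = [
    "classify_patient",
    "classify_cohort",
    "dual_marker_classify",
    "dual_marker_classify_cohort",
    "classify_arrays",
    "record_from_row",
    "DEFAULT_PRECEDENCE",
    "TriageInputError",
]

logger = logging.getLogger(__name__)

DEFAULT_PRECEDENCE: Tuple[str, ...] = (
    "rulein_0h",
    "ruleout_single",
    "rulein_delta",
    "ruleout_paired",
)

_ZERO_H_STEPS = frozenset({"rulein_0h", "ruleout_single"})


class TriageInputError(ValueError):
    """A record lacks the inputs a rule set requires."""


def _delta(c0: float, c1: float, convention: str) -> float:
    d = c1 - c0
    return abs(d) if convention == "unsigned" else d


def _check_concentration(value: float, what: str, patient: str) -> None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise TriageInputError(f"patient {patient}: missing {what}")
    if value < 0:
        raise ValidationError(f"patient {patient}: negative {what} ({value})")


def classify_patient(
    record: PatientRecord,
    spec: AlgorithmSpec,
    *,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> TriageResult:
    """Deterministically triage one patient under ``spec``.

    Raises :class:`TriageInputError` when the 0 h value for the rule set's
    marker (or the onset interval, for an onset-gated rule set) is missing,
    and :class:`~myotriage.models.ValidationError` on negative
    concentrations.
    """
    if sorted(precedence) != sorted(DEFAULT_PRECEDENCE):
        raise ValidationError(
            f"precedence must be a permutation of {DEFAULT_PRECEDENCE}"
        )
    if precedence != DEFAULT_PRECEDENCE:
        logger.debug("non-default criterion precedence %s", precedence)

    marker = spec.marker
    if marker not in record.c0:
        raise TriageInputError(
            f"patient {record.id}: no 0 h {marker} value for rule set {spec.name!r}"
        )
    c0 = record.c0[marker]
    _check_concentration(c0, f"0 h {marker}", record.id)

    has_c1 = marker in record.c1 and record.c1[marker] is not None
    c1 = record.c1.get(marker) if has_c1 else None
    if has_c1 and isinstance(c1, float) and math.isnan(c1):
        has_c1, c1 = False, None
    if has_c1:
        _check_concentration(c1, f"1 h {marker}", record.id)
        delta = _delta(c0, c1, spec.delta_convention)
    else:
        delta = None

    gate = spec.ruleout_single_requires_onset_gt
    if gate is not None and record.onset_hours is None:
        raise TriageInputError(
            f"patient {record.id}: rule set {spec.name!r} gates the single-sample "
            "rule-out on onset, but onset_hours is missing"
        )

    for step in precedence:
        if step == "rulein_0h":
            if c0 >= spec.rulein_0h:
                return TriageResult(
                    TriageCategory.RULE_IN, DecisionBasis.ZERO_H_ONLY, "RULE_IN_0H"
                )
        elif step == "ruleout_single":
            gate_ok = gate is None or record.onset_hours > gate
            if gate_ok and c0 < spec.ruleout_single_0h:
                return TriageResult(
                    TriageCategory.RULE_OUT,
                    DecisionBasis.ZERO_H_ONLY,
                    "RULE_OUT_SINGLE_0H",
                )
        elif step == "rulein_delta":
            if delta is not None and delta >= spec.rulein_delta:
                return TriageResult(
                    TriageCategory.RULE_IN, DecisionBasis.ZERO_ONE_H, "RULE_IN_DELTA"
                )
        elif step == "ruleout_paired":
            if (
                delta is not None
                and c0 < spec.ruleout_paired_0h
                and delta < spec.ruleout_paired_delta
            ):
                return TriageResult(
                    TriageCategory.RULE_OUT,
                    DecisionBasis.ZERO_ONE_H,
                    "RULE_OUT_PAIRED",
                )

    if delta is None:
        return TriageResult(
            TriageCategory.INDETERMINATE, DecisionBasis.ZERO_H_ONLY, "NO_1H_SAMPLE"
        )
    return TriageResult(TriageCategory.OBSERVE, DecisionBasis.ZERO_ONE_H, "OBSERVE")


def record_from_row(row) -> PatientRecord:
    """Build a :class:`PatientRecord` from one cohort-table row."""
    c0, c1 = {}, {}
    for marker in ("cmyc", "tnt", "tni"):
        v0 = getattr(row, f"{marker}_0h", None)
        v1 = getattr(row, f"{marker}_1h", None)
        if v0 is not None and not (isinstance(v0, float) and math.isnan(v0)):
            c0[marker] = float(v0)
        if v1 is not None and not (isinstance(v1, float) and math.isnan(v1)):
            c1[marker] = float(v1)
    nstemi = getattr(row, "nstemi", None)
    follow_up = getattr(row, "follow_up_days", None)
    covariates = {
        k: getattr(row, k) for k in ("age", "sex", "renal_disease") if hasattr(row, k)
    }
    return PatientRecord(
        id=str(row.id),
        c0=c0,
        c1=c1,
        onset_hours=_opt_float(getattr(row, "onset_hours", None)),
        nstemi=None if nstemi is None else bool(nstemi),
        follow_up_days=_opt_float(follow_up),
        died=bool(getattr(row, "died", False)),
        covariates=covariates,
    )


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def classify_cohort(
    cohort: pd.DataFrame,
    spec: AlgorithmSpec,
    *,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Triage every record; returns a table with one row per patient.

    Columns: ``id``, ``category``, ``basis``, ``fired_criterion`` and, when
    the cohort is labelled, ``nstemi``.  Per-record failures are re-raised
    with the patient id in the message.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot classify an empty cohort")
    rows = []
    for row in cohort.itertuples(index=False):
        record = record_from_row(row)
        try:
            result = classify_patient(record, spec, precedence=precedence)
        except (TriageInputError, ValidationError):
            raise
        rows.append(
            {
                "id": record.id,
                "category": result.category.value,
                "basis": result.basis.value,
                "fired_criterion": result.fired_criterion,
                **({"nstemi": int(record.nstemi)} if record.nstemi is not None else {}),
            }
        )
    return pd.DataFrame(rows)


def dual_marker_classify(
    record: PatientRecord,
    esc_spec: AlgorithmSpec,
    booster: AlgorithmSpec,
) -> TriageResult:
    """Troponin algorithm with an added 0 h booster-marker layer.

    The booster's 0 h-only criteria (single-sample rule-out; 0 h rule-in)
    act as alternative ("or") direct criteria alongside the base rule set's
    own 0 h criteria; when no 0 h criterion fires, the base 0/1 h logic
    decides.  With sentinel booster thresholds (0, inf) the output is
    identical to the base rule set alone.
    """
    for marker, spec_ in ((esc_spec.marker, esc_spec), (booster.marker, booster)):
        if marker not in record.c0:
            raise TriageInputError(
                f"patient {record.id}: no 0 h {marker} value for rule set "
                f"{spec_.name!r}"
            )
    c0_esc = record.c0[esc_spec.marker]
    c0_b = record.c0[booster.marker]
    _check_concentration(c0_esc, f"0 h {esc_spec.marker}", record.id)
    _check_concentration(c0_b, f"0 h {booster.marker}", record.id)

    # 0 h rule-in: base criterion first, booster as the alternative branch
    if c0_esc >= esc_spec.rulein_0h:
        return TriageResult(
            TriageCategory.RULE_IN, DecisionBasis.ZERO_H_ONLY, "RULE_IN_0H"
        )
    if c0_b >= booster.rulein_0h:
        return TriageResult(
            TriageCategory.RULE_IN, DecisionBasis.ZERO_H_ONLY, "BOOSTER_RULE_IN_0H"
        )
    # 0 h rule-out, with each rule set's own onset gating
    esc_gate = esc_spec.ruleout_single_requires_onset_gt
    if esc_gate is not None and record.onset_hours is None:
        raise TriageInputError(
            f"patient {record.id}: rule set {esc_spec.name!r} gates the "
            "single-sample rule-out on onset, but onset_hours is missing"
        )
    if (esc_gate is None or record.onset_hours > esc_gate) and (
        c0_esc < esc_spec.ruleout_single_0h
    ):
        return TriageResult(
            TriageCategory.RULE_OUT, DecisionBasis.ZERO_H_ONLY, "RULE_OUT_SINGLE_0H"
        )
    b_gate = booster.ruleout_single_requires_onset_gt
    if (b_gate is None or (record.onset_hours is not None and record.onset_hours > b_gate)) and (
        c0_b < booster.ruleout_single_0h
    ):
        return TriageResult(
            TriageCategory.RULE_OUT,
            DecisionBasis.ZERO_H_ONLY,
            "BOOSTER_RULE_OUT_SINGLE_0H",
        )
    # neither 0 h layer fired: the base rule set's delta logic decides
    result = classify_patient(record, esc_spec)
    if result.basis is DecisionBasis.ZERO_H_ONLY and result.category in (
        TriageCategory.RULE_OUT,
        TriageCategory.RULE_IN,
    ):  # pragma: no cover - unreachable: 0 h criteria were already checked
        raise AssertionError("base 0 h criterion resolved after layering")
    return result


def dual_marker_classify_cohort(
    cohort: pd.DataFrame, esc_spec: AlgorithmSpec, booster: AlgorithmSpec
) -> pd.DataFrame:
    """Vector version of :func:`dual_marker_classify` over a cohort table."""
    if len(cohort) == 0:
        raise ValidationError("cannot classify an empty cohort")
    rows = []
    for row in cohort.itertuples(index=False):
        record = record_from_row(row)
        result = dual_marker_classify(record, esc_spec, booster)
        rows.append(
            {
                "id": record.id,
                "category": result.category.value,
                "basis": result.basis.value,
                "fired_criterion": result.fired_criterion,
                **({"nstemi": int(record.nstemi)} if record.nstemi is not None else {}),
            }
        )
    return pd.DataFrame(rows)


# integer codes shared with the derivation search
CATEGORY_CODES = {
    TriageCategory.RULE_OUT: 0,
    TriageCategory.OBSERVE: 1,
    TriageCategory.RULE_IN: 2,
    TriageCategory.INDETERMINATE: 3,
}
BASIS_CODES = {DecisionBasis.ZERO_H_ONLY: 0, DecisionBasis.ZERO_ONE_H: 1}


def classify_arrays(
    c0: np.ndarray,
    c1: np.ndarray,
    onset: Optional[np.ndarray],
    spec: AlgorithmSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised triage of concentration arrays under the default precedence.

    ``c1`` may contain NaN for missing 1 h samples.  Returns
    ``(category_codes, basis_codes)`` with the encodings of
    :data:`CATEGORY_CODES` / :data:`BASIS_CODES`.  Semantically identical to
    :func:`classify_patient` row by row (property-tested).
    """
    c0 = np.asarray(c0, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    if np.any(np.isnan(c0)) or np.any(c0 < 0):
        raise ValidationError("0 h concentrations must be present and non-negative")
    if np.any(c1 < 0):
        raise ValidationError("1 h concentrations must be non-negative")
    has_c1 = ~np.isnan(c1)
    delta = np.where(has_c1, c1 - c0, np.nan)
    if spec.delta_convention == "unsigned":
        delta = np.abs(delta)

    gate = spec.ruleout_single_requires_onset_gt
    if gate is not None:
        if onset is None:
            raise TriageInputError(
                f"rule set {spec.name!r} gates on onset but onset is missing"
            )
        gate_ok = np.asarray(onset, dtype=float) > gate
    else:
        gate_ok = np.ones_like(c0, dtype=bool)

    cat = np.full(c0.shape, CATEGORY_CODES[TriageCategory.OBSERVE], dtype=np.int8)
    basis = np.full(c0.shape, BASIS_CODES[DecisionBasis.ZERO_ONE_H], dtype=np.int8)
    undecided = np.ones_like(c0, dtype=bool)

    step = undecided & (c0 >= spec.rulein_0h)
    cat[step] = CATEGORY_CODES[TriageCategory.RULE_IN]
    basis[step] = BASIS_CODES[DecisionBasis.ZERO_H_ONLY]
    undecided &= ~step

    step = undecided & gate_ok & (c0 < spec.ruleout_single_0h)
    cat[step] = CATEGORY_CODES[TriageCategory.RULE_OUT]
    basis[step] = BASIS_CODES[DecisionBasis.ZERO_H_ONLY]
    undecided &= ~step

    step = undecided & ~has_c1
    cat[step] = CATEGORY_CODES[TriageCategory.INDETERMINATE]
    basis[step] = BASIS_CODES[DecisionBasis.ZERO_H_ONLY]
    undecided &= ~step

    with np.errstate(invalid="ignore"):
        step = undecided & (delta >= spec.rulein_delta)
        cat[step] = CATEGORY_CODES[TriageCategory.RULE_IN]
        undecided &= ~step

        step = (
            undecided
            & (c0 < spec.ruleout_paired_0h)
            & (delta < spec.ruleout_paired_delta)
        )
        cat[step] = CATEGORY_CODES[TriageCategory.RULE_OUT]
    return cat, basis
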
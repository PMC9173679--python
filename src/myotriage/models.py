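"""Shared domain types for 0/1h biomarker triage analysis.

The vocabulary follows the clinical literature on rapid rule-out/rule-in
algorithms for suspected NSTEMI: a patient presents to the emergency
department with chest discomfort, a cardiac biomarker is measured at
presentation (0 h) and again one hour later, and a threshold rule set
assigns one of three mutually exclusive triage categories.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence


class TriageCategory(str, Enum):
    RULE_OUT = "rule_out"
    OBSERVE = "observe"
    RULE_IN = "rule_in"
    INDETERMINATE = "indeterminate"


class DecisionBasis(str, Enum):
    """Whether a triage decision needed the 1 h sample."""

    ZERO_H_ONLY = "0h"
    ZERO_ONE_H = "0/1h"


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class TriageResult:
    category: TriageCategory
    basis: DecisionBasis
    fired_criterion: str


@dataclass(frozen=True)
class QuartileAnchor:
    """Printed [1st quartile; median; 3rd quartile] triplet in ng/L."""

    q1: float
    median: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median:
            raise ValidationError(
                f"q1 ({self.q1}) must not exceed median ({self.median})"
            )
        if not self.median <= self.q3:
            raise ValidationError(
                f"median ({self.median}) must not exceed q3 ({self.q3})"
            )

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.q1, self.median, self.q3)


@dataclass
class PatientRecord:
    """One subject: serial biomarker values, onset interval, label, follow-up.

    ``c0``/``c1`` map a marker name (``cmyc``, ``tnt``, ``tni``) to its
    concentration in ng/L; a marker absent from ``c1`` means the 1 h sample
    was not obtained.
    """

    id: str
    c0: Mapping[str, float]
    c1: Mapping[str, float] = field(default_factory=dict)
    onset_hours: Optional[float] = None
    nstemi: Optional[bool] = None
    follow_up_days: Optional[float] = None
    died: bool = False
    covariates: Mapping[str, object] = field(default_factory=dict)


_FINITE_OR_INF = (int, float)


@dataclass
class AlgorithmSpec:
    """A complete 0/1h triage rule set.

    Boundary semantics follow the clinical wording: rule-out thresholds are
    strict ("below"), rule-in thresholds are inclusive ("at least").  The
    ``delta_convention`` decides whether the 0/1 h change is taken signed
    (a fall can never trigger rule-in) or as an unsigned magnitude.
    ``ruleout_single_requires_onset_gt`` gates the single-sample rule-out on
    time since chest-pain onset (hours); ``None`` applies it irrespective of
    onset.  Rule-in slots may be ``inf`` (never fires) so that a neutral
    booster spec can be expressed.
    """

    name: str
    marker: str
    ruleout_single_0h: float
    ruleout_paired_0h: float
    ruleout_paired_delta: float
    rulein_0h: float
    rulein_delta: float
    delta_convention: str = "signed"
    ruleout_single_requires_onset_gt: Optional[float] = None

    def __post_init__(self) -> None:
        for slot in (
            "ruleout_single_0h",
            "ruleout_paired_0h",
            "ruleout_paired_delta",
            "rulein_0h",
            "rulein_delta",
        ):
            value = getattr(self, slot)
            if not isinstance(value, _FINITE_OR_INF) or math.isnan(value):
                raise ValidationError(f"{slot} must be a number, got {value!r}")
            if value < 0:
                raise ValidationError(f"{slot} must be non-negative, got {value}")
        if self.ruleout_single_0h > self.ruleout_paired_0h:
            raise ValidationError(
                "ruleout_single_0h must not exceed ruleout_paired_0h "
                f"({self.ruleout_single_0h} > {self.ruleout_paired_0h})"
            )
        if not self.ruleout_paired_0h < self.rulein_0h:
            raise ValidationError(
                "ruleout_paired_0h must be strictly below rulein_0h "
                f"({self.ruleout_paired_0h} >= {self.rulein_0h})"
            )
        if self.ruleout_paired_delta > self.rulein_delta:
            raise ValidationError(
                "ruleout_paired_delta must not exceed rulein_delta "
                f"({self.ruleout_paired_delta} > {self.rulein_delta})"
            )
        if self.delta_convention not in ("signed", "unsigned"):
            raise ValidationError(
                f"delta_convention must be 'signed' or 'unsigned', "
                f"got {self.delta_convention!r}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "marker": self.marker,
            "ruleout_single_0h": self.ruleout_single_0h,
            "ruleout_paired_0h": self.ruleout_paired_0h,
            "ruleout_paired_delta": self.ruleout_paired_delta,
            "rulein_0h": self.rulein_0h,
            "rulein_delta": self.rulein_delta,
            "delta_convention": self.delta_convention,
            "ruleout_single_requires_onset_gt": self.ruleout_single_requires_onset_gt,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "AlgorithmSpec":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in data.items() if k in known})


#: The published cMyC 0/1h rule set: rule-out below 10 ng/L at presentation
#: (irrespective of chest-pain onset) or below 18 ng/L with a signed 0/1 h
#: increase < 4 ng/L; rule-in at >= 140 ng/L or a 0/1 h increase >= 15 ng/L.
CMYC_01H = AlgorithmSpec(
    name="cmyc-0/1h",
    marker="cmyc",
    ruleout_single_0h=10.0,
    ruleout_paired_0h=18.0,
    ruleout_paired_delta=4.0,
    rulein_0h=140.0,
    rulein_delta=15.0,
    delta_convention="signed",
    ruleout_single_requires_onset_gt=None,
)


@dataclass(frozen=True)
class PerformanceTargets:
    """Pre-defined derivation targets: NPV >= 99%, sensitivity >= 99%,
    PPV >= 70%."""

    min_npv: float = 0.99
    min_sensitivity: float = 0.99
    min_ppv: float = 0.70

    def __post_init__(self) -> None:
        for name in ("min_npv", "min_sensitivity", "min_ppv"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class GridSpec:
    """Candidate threshold values for the five slots of an AlgorithmSpec."""

    ruleout_single_0h: Sequence[float]
    ruleout_paired_0h: Sequence[float]
    ruleout_paired_delta: Sequence[float]
    rulein_0h: Sequence[float]
    rulein_delta: Sequence[float]

    def __post_init__(self) -> None:
        for slot in self.__dataclass_fields__:  # type: ignore[attr-defined]
            values = list(getattr(self, slot))
            if not values:
                raise ValidationError(f"grid slot {slot} is empty")
            if any(v <= 0 for v in values):
                raise ValidationError(f"grid slot {slot} has non-positive values")
            if sorted(values) != values:
                raise ValidationError(f"grid slot {slot} must be ascending")
            setattr(self, slot, values)

    @property
    def n_combinations(self) -> int:
        out = 1
        for slot in self.__dataclass_fields__:  # type: ignore[attr-defined]
            out *= len(getattr(self, slot))
        return out

    def to_dict(self) -> dict:
        return {slot: list(getattr(self, slot)) for slot in self.__dataclass_fields__}  # type: ignore[attr-defined]

    @classmethod
    def from_dict(cls, data: Mapping[str, Sequence[float]]) -> "GridSpec":
        return cls(**{k: list(v) for k, v in data.items()})


def default_grid() -> GridSpec:
    """Integer ng/L steps: [2, 30] for the rule-out slots, [50, 300] step 10
    for the 0 h rule-in and [5, 50] step 1 for the rule-in delta."""
    return GridSpec(
        ruleout_single_0h=[float(v) for v in range(2, 31)],
        ruleout_paired_0h=[float(v) for v in range(2, 31)],
        ruleout_paired_delta=[float(v) for v in range(2, 31)],
        rulein_0h=[float(v) for v in range(50, 301, 10)],
        rulein_delta=[float(v) for v in range(5, 51)],
    )


@dataclass(frozen=True)
class MetricEstimate:
    """A point estimate with its interval and the estimation method."""

    value: float
    lower: float
    upper: float
    method: str  # JEFFREYS | WILSON | PLUGIN
    n_effective: int
    defined: bool = True
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.lower, self.upper)

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "lower": self.lower,
            "upper": self.upper,
            "method": self.method,
            "n_effective": self.n_effective,
            "defined": self.defined,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class TriageConfusion:
    """Per-category NSTEMI-positive/negative counts (3x2 table), with
    indeterminate patients carried separately so denominators stay explicit."""

    ruleout_pos: int
    ruleout_neg: int
    observe_pos: int
    observe_neg: int
    rulein_pos: int
    rulein_neg: int
    indeterminate_pos: int = 0
    indeterminate_neg: int = 0

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:  # type: ignore[attr-defined]
            if getattr(self, f) < 0:
                raise ValidationError(f"count {f} is negative")

    @property
    def positives(self) -> int:
        return (
            self.ruleout_pos + self.observe_pos + self.rulein_pos + self.indeterminate_pos
        )

    @property
    def negatives(self) -> int:
        return (
            self.ruleout_neg + self.observe_neg + self.rulein_neg + self.indeterminate_neg
        )

    @property
    def n(self) -> int:
        return self.positives + self.negatives

    @property
    def ruleout_total(self) -> int:
        return self.ruleout_pos + self.ruleout_neg

    @property
    def observe_total(self) -> int:
        return self.observe_pos + self.observe_neg

    @property
    def rulein_total(self) -> int:
        return self.rulein_pos + self.rulein_neg

    @property
    def indeterminate_total(self) -> int:
        return self.indeterminate_pos + self.indeterminate_neg
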
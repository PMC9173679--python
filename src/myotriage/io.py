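"""Cohort and configuration file I/O.

The cohort interchange format is plain CSV (RFC 4180, header row, "."
decimal separator) with the documented column dictionary:

=================  =====================================================
column             meaning
=================  =====================================================
id                 opaque patient identifier (string, unique)
cmyc_0h, cmyc_1h   cMyC concentration ng/L at presentation / 1 h
tnt_0h,  tnt_1h    hs-cTnT concentration ng/L
tni_0h,  tni_1h    hs-cTnI concentration ng/L
onset_hours        hours from chest-pain onset to presentation
nstemi             adjudicated label, 0/1
follow_up_days     days to death or censoring
died               0/1 (1 = death at follow_up_days)
age                years
sex                "female"/"male"
renal_disease      0/1
=================  =====================================================

Missing 1 h samples are encoded as an empty field.  Rule sets, grids,
targets and simulation parameters travel as YAML.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .models import AlgorithmSpec, GridSpec, PerformanceTargets, ValidationError

__all__ = [
    "read_cohort",
    "write_cohort",
    "load_algorithm",
    "dump_algorithm",
    "load_grid",
    "load_targets",
    "SchemaError",
    "CohortValidationError",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "template_path",
]

PathLike = Union[str, Path]

REQUIRED_COLUMNS = ("id", "cmyc_0h", "cmyc_1h", "onset_hours", "nstemi")
OPTIONAL_COLUMNS = (
    "tnt_0h",
    "tnt_1h",
    "tni_0h",
    "tni_1h",
    "follow_up_days",
    "died",
    "age",
    "sex",
    "renal_disease",
)
_CONCENTRATION_COLUMNS = ("cmyc_0h", "cmyc_1h", "tnt_0h", "tnt_1h", "tni_0h", "tni_1h")
_ZERO_H_COLUMNS = ("cmyc_0h",)


class SchemaError(ValidationError):
    """The file does not match the documented column dictionary."""


class CohortValidationError(ValidationError):
    """Rows violate the cohort invariants; carries 1-based file line numbers."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        shown = "; ".join(f"line {line}: {msg}" for line, msg in problems[:20])
        more = "" if len(problems) <= 20 else f" (+{len(problems) - 20} more)"
        super().__init__(f"invalid cohort rows: {shown}{more}")


def validate_cohort(frame: pd.DataFrame, *, header_offset: int = 2) -> dict:
    """Check cohort invariants; returns a small info dict (missing-1h counts).

    ``header_offset`` maps frame row 0 to its file line (2 when the frame
    came straight from a headered CSV).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort file lacks mandatory columns: {missing}")
    problems: list[tuple[int, str]] = []
    for col in _CONCENTRATION_COLUMNS:
        if col not in frame.columns:
            continue
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals < 0]
        problems += [(int(i) + header_offset, f"negative {col} ({frame[col][i]})") for i in bad]
    for col in _ZERO_H_COLUMNS:
        bad = frame.index[frame[col].isna()]
        problems += [(int(i) + header_offset, f"missing {col}") for i in bad]
    if "onset_hours" in frame.columns:
        bad = frame.index[pd.to_numeric(frame["onset_hours"], errors="coerce") < 0]
        problems += [(int(i) + header_offset, "negative onset_hours") for i in bad]
    if "follow_up_days" in frame.columns:
        bad = frame.index[pd.to_numeric(frame["follow_up_days"], errors="coerce") < 0]
        problems += [(int(i) + header_offset, "negative follow_up_days") for i in bad]
    if frame["id"].duplicated().any():
        dupes = frame.loc[frame["id"].duplicated(), "id"].tolist()[:5]
        problems.append((0, f"duplicate ids {dupes}"))
    if problems:
        raise CohortValidationError(sorted(problems))
    info = {
        "n": int(len(frame)),
        "n_missing_1h": {
            c: int(frame[c].isna().sum()) for c in _CONCENTRATION_COLUMNS
            if c.endswith("_1h") and c in frame.columns
        },
    }
    return info


def read_cohort(path: PathLike) -> pd.DataFrame:
    """Read and validate a cohort CSV; missing-1h counts land in ``.attrs``."""
    frame = pd.read_csv(path, dtype={"id": str, "sex": str})
    info = validate_cohort(frame)
    frame.attrs["cohort_info"] = info
    return frame


def write_cohort(frame: pd.DataFrame, path: PathLike) -> None:
    """Write a cohort CSV (empty fields for missing values; lossless floats)."""
    frame.to_csv(path, index=False)


def load_algorithm(path: PathLike) -> AlgorithmSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping of rule-set fields")
    data = {
        k: (float("inf") if v in (".inf", "inf") else v) for k, v in data.items()
    }
    return AlgorithmSpec.from_dict(data)


def dump_algorithm(spec: AlgorithmSpec, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_grid(path: PathLike) -> GridSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return GridSpec.from_dict(data)


def load_targets(path: PathLike) -> PerformanceTargets:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(PerformanceTargets)}
    return PerformanceTargets(**{k: v for k, v in data.items() if k in fields})


def template_path(name: str) -> Path:
    """Path of a bundled rule-set template (e.g. ``esc_hstnt_01h``)."""
    p = Path(__file__).parent / "templates" / f"{name}.yaml"
    if not p.exists():
        available = sorted(q.stem for q in p.parent.glob("*.yaml"))
        raise FileNotFoundError(f"no template {name!r}; available: {available}")
    return p
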
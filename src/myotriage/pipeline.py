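"""End-to-end analysis flow: simulate (or load) → split → derive → validate
→ compare → prognosis.

Every numeric output is fully determined by the seed and the configuration;
the manifest records both (plus a hash of the canonical configuration), so
two runs with the same config produce byte-identical manifests.  All
report percentages are stored as integer counts next to their rendered
strings, keeping the arithmetic auditable.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .derivation import DerivationResult, derive_optimal
from .io import load_algorithm, read_cohort, template_path, write_cohort, dump_algorithm
from .metrics import performance_report, report_to_frame
from .models import (
    AlgorithmSpec,
    CMYC_01H,
    GridSpec,
    PerformanceTargets,
    ValidationError,
    default_grid,
)
from .simulate import SimulationParams, default_params, sample_cohort, split_cohort
from .survival import survival_by_category
from .triage import classify_cohort, dual_marker_classify_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    With ``cohort_path`` unset, a synthetic cohort of ``n`` patients is
    generated under the default study conditions.  ``subgroup`` may be
    ``"early"`` (onset <= 3 h) or a pandas query string over the cohort
    columns; the subgroup report is computed on the validation set only.
    """

    seed: int = 1
    n: int = 2000
    cohort_path: Optional[str] = None
    split_ratio: float = 0.5
    targets: PerformanceTargets = field(default_factory=PerformanceTargets)
    grid: Optional[GridSpec] = None
    derive: bool = True
    algorithms: Dict[str, str] = field(
        default_factory=lambda: {
            "esc_hstnt": "template:esc_hstnt_01h",
            "esc_hstni": "template:esc_hstni_01h",
        }
    )
    dual_marker: bool = True
    subgroup: Optional[str] = "early"
    horizons: List[float] = field(default_factory=lambda: [30.0, 365.0])
    outdir: Optional[str] = None

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "n": self.n,
            "cohort_path": self.cohort_path,
            "split_ratio": self.split_ratio,
            "targets": {
                "min_npv": self.targets.min_npv,
                "min_sensitivity": self.targets.min_sensitivity,
                "min_ppv": self.targets.min_ppv,
            },
            "grid": self.grid.to_dict() if self.grid else "default",
            "derive": self.derive,
            "algorithms": dict(self.algorithms),
            "dual_marker": self.dual_marker,
            "subgroup": self.subgroup,
            "horizons": list(self.horizons),
        }


def _resolve_algorithm(ref: str) -> AlgorithmSpec:
    if ref.startswith("template:"):
        return load_algorithm(template_path(ref.split(":", 1)[1]))
    return load_algorithm(ref)


def _early_mask(cohort: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "early":
        return cohort["onset_hours"] <= 3.0
    return cohort.eval(subgroup)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) the bundle."""
    stages: Dict[str, dict] = {}

    def stage(name: str, **info):
        logger.info("stage %s: %s", name, info)
        stages[name] = info

    # ------------------------------------------------------------------ data
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
        source = {
            "loaded": str(config.cohort_path),
            "n_missing_1h": cohort.attrs["cohort_info"]["n_missing_1h"],
        }
    else:
        params = default_params(n=config.n, seed=config.seed)
        cohort = sample_cohort(params)
        source = {"simulated": True, "prevalence": params.prevalence}
    stage("cohort", n=len(cohort), n_nstemi=int(cohort["nstemi"].sum()), **source)

    derivation_set, validation_set = split_cohort(
        cohort, config.split_ratio, seed=config.seed
    )
    stage("split", n_derivation=len(derivation_set), n_validation=len(validation_set))

    # ------------------------------------------------------------ derivation
    derived: Optional[DerivationResult] = None
    if config.derive:
        grid = config.grid or default_grid()
        derived = derive_optimal(derivation_set, config.targets, grid)
        stage(
            "derive",
            feasible=derived.feasible,
            method=derived.method,
            n_valid_combinations=derived.n_valid_combinations,
            spec=derived.spec.to_dict() if derived.spec else None,
        )

    # ------------------------------------------------------------ validation
    specs: Dict[str, AlgorithmSpec] = {}
    if derived is not None and derived.feasible:
        specs["cmyc_derived"] = derived.spec
    specs["cmyc_reference"] = CMYC_01H
    for name, ref in config.algorithms.items():
        specs[name] = _resolve_algorithm(ref)

    tables = {name: classify_cohort(validation_set, s) for name, s in specs.items()}
    if config.dual_marker:
        booster = CMYC_01H
        for name in list(config.algorithms):
            tables[f"{name}_plus_cmyc"] = dual_marker_classify_cohort(
                validation_set, specs[name], booster
            )
    reference = "cmyc_derived" if "cmyc_derived" in tables else "cmyc_reference"
    report = performance_report(tables, reference=reference)
    stage("validate", algorithms=list(tables), reference=reference)

    subgroup_report = None
    if config.subgroup:
        mask = _early_mask(validation_set, config.subgroup)
        sub = validation_set[mask].reset_index(drop=True)
        if len(sub) and sub["nstemi"].nunique() > 0:
            sub_tables = {
                name: classify_cohort(sub, s) for name, s in specs.items()
            }
            subgroup_report = performance_report(sub_tables, reference=reference)
            subgroup_report["subgroup"] = config.subgroup
        stage("subgroup", expression=config.subgroup, n=int(mask.sum()))

    # -------------------------------------------------------------- survival
    survival = None
    if "follow_up_days" in validation_set.columns:
        km, tests = survival_by_category(
            validation_set, tables[reference], horizons=config.horizons
        )
        survival = {
            "milestones": {
                label: est.milestones.to_dict(orient="records")
                for label, est in km.items()
            },
            "logrank": {str(h): res.to_dict() for h, res in tests.items()},
        }
        stage("prognosis", strata={k: v.n for k, v in km.items()})

    manifest = {
        "package": "myotriage",
        "version": __version__,
        "seed": config.seed,
        "config": config.canonical(),
        "config_hash": hashlib.sha256(
            json.dumps(config.canonical(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": stages,
    }
    bundle = {
        "manifest": manifest,
        "report": report,
        "subgroup_report": subgroup_report,
        "survival": survival,
        "derivation": None
        if derived is None
        else {
            "feasible": derived.feasible,
            "spec": derived.spec.to_dict() if derived.spec else None,
            "summary": derived.summary.to_dict() if derived.summary else None,
            "infeasibility": derived.infeasibility,
            "n_valid_combinations": derived.n_valid_combinations,
            "method": derived.method,
        },
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if not config.cohort_path:
            write_cohort(cohort, outdir / "cohort.csv")
        for name, table in tables.items():
            table.to_csv(outdir / f"triage_{name}.csv", index=False)
        if derived is not None and derived.spec is not None:
            dump_algorithm(derived.spec, outdir / "derived_spec.yaml")
        report_to_frame(report).to_csv(outdir / "report.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(bundle["report"]), fh, indent=2, sort_keys=True)
        if survival is not None:
            with open(outdir / "survival.json", "w") as fh:
                json.dump(_jsonable(survival), fh, indent=2, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    return bundle


def _jsonable(obj):
    """Recursively coerce numpy scalars so json.dump succeeds."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
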
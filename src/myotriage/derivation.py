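"""Derive an optimal 0/1h threshold combination on a derivation cohort.

The derivation emulates the published procedure: over a candidate grid of
the five threshold slots (single-sample rule-out, paired rule-out 0 h,
rule-out delta, rule-in 0 h, rule-in delta), find the combination that
satisfies pre-defined performance targets — NPV and sensitivity in the
rule-out group, PPV in the rule-in group — and, among the feasible ones,
maximises triage efficacy (the proportion of patients not left in the
observe zone).  Constraint metrics use the same estimators as the
reporting layer (Jeffreys NPV/PPV, raw sensitivity), so a derived rule set
re-evaluated on the same cohort satisfies the targets exactly as
constrained.

Two search strategies produce provably identical results:

* ``exhaustive`` — enumerate every valid combination (used for small grids
  and as the oracle in tests);
* ``decomposed`` — an exact factorisation: rule-out group composition
  depends only on (single, paired 0 h, rule-out delta), rule-in composition
  only on (single, rule-in 0 h, rule-in delta), and the feasibility
  constraints are group-local, so the two sides can be optimised from
  precomputed count tables.  This makes the ~29-million-combination default
  grid tractable without excluding any optimum.

Ties are broken deterministically: greater rule-out count, then higher
0 h rule-in threshold, then lexicographically smallest remaining slots.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import build_confusion, group_metrics
from .models import (
    AlgorithmSpec,
    GridSpec,
    MetricEstimate,
    PerformanceTargets,
    TriageConfusion,
    ValidationError,
)
from .triage import classify_cohort

__all__ = ["evaluate_threshold_set", "derive_optimal", "ThresholdSummary", "DerivationResult"]


@dataclass
class ThresholdSummary:
    """Performance of one rule set on one labelled cohort."""

    spec: AlgorithmSpec
    confusion: TriageConfusion
    metrics: Dict[str, MetricEstimate]

    @property
    def efficacy_count(self) -> int:
        return self.confusion.ruleout_total + self.confusion.rulein_total

    def meets(self, targets: PerformanceTargets) -> bool:
        sens = self.metrics["sensitivity"]
        npv = self.metrics["npv"]
        ppv = self.metrics["ppv"]
        return (
            sens.defined
            and npv.defined
            and ppv.defined
            and sens.value >= targets.min_sensitivity
            and npv.value >= targets.min_npv
            and ppv.value >= targets.min_ppv
        )

    def to_dict(self) -> dict:
        c = self.confusion
        return {
            "spec": self.spec.to_dict(),
            "counts": {
                "rule_out": c.ruleout_total,
                "observe": c.observe_total,
                "rule_in": c.rulein_total,
                "indeterminate": c.indeterminate_total,
                "rule_out_pos": c.ruleout_pos,
                "rule_in_pos": c.rulein_pos,
                "n": c.n,
            },
            "metrics": {k: v.to_dict() for k, v in self.metrics.items()},
        }


def evaluate_threshold_set(
    cohort: pd.DataFrame, spec: AlgorithmSpec, conf_level: float = 0.95
) -> ThresholdSummary:
    """Classify a labelled cohort under ``spec`` and summarise performance.

    Empty groups yield metrics flagged undefined (a PPV with no rule-in
    patients is not zero).
    """
    table = classify_cohort(cohort, spec)
    confusion = build_confusion(table)
    return ThresholdSummary(spec, confusion, group_metrics(confusion, conf_level))


@dataclass
class DerivationResult:
    feasible: bool
    spec: Optional[AlgorithmSpec]
    summary: Optional[ThresholdSummary]
    audit: pd.DataFrame
    n_valid_combinations: int
    objective: str
    method: str
    #: when infeasible: per-constraint best values achieved anywhere on the
    #: grid plus the unconstrained-efficacy maximiser's summary
    infeasibility: Optional[dict] = None


def _combo_feasibility(
    ro_pos, ro_neg, ri_pos, ri_neg, positives: int, targets: PerformanceTargets
):
    """Constraint metrics from group counts; shared by both search modes so
    that feasibility decisions are bit-identical."""
    sens = (positives - ro_pos) / positives
    npv = (ro_neg + 0.5) / (ro_pos + ro_neg + 1.0)
    ppv = (ri_pos + 0.5) / (ri_pos + ri_neg + 1.0)
    ok = (
        (sens >= targets.min_sensitivity)
        & (npv >= targets.min_npv)
        & (ppv >= targets.min_ppv)
    )
    return sens, npv, ppv, ok


_KEY_COLS = ("ruleout_single_0h", "ruleout_paired_0h", "ruleout_paired_delta", "rulein_0h", "rulein_delta")


def _candidate_key(objective: str, eff: int, ro: int, combo: Tuple[float, ...]):
    a, b, dout, r0, din = combo
    if objective == "efficacy":
        return (-eff, -ro, -r0, a, b, dout, din)
    if objective == "rule_out":
        return (-ro, -eff, -r0, a, b, dout, din)
    raise ValidationError(f"unknown objective {objective!r}")


def _extract_arrays(cohort: pd.DataFrame, marker: str, delta_convention: str):
    col0, col1 = f"{marker}_0h", f"{marker}_1h"
    for col in (col0, col1, "nstemi"):
        if col not in cohort.columns:
            raise ValidationError(f"cohort lacks required column {col!r}")
    c0 = cohort[col0].to_numpy(dtype=float)
    c1 = cohort[col1].to_numpy(dtype=float)
    if np.isnan(c0).any() or np.isnan(c1).any():
        raise ValidationError(
            "derivation requires complete 0 h and 1 h measurements"
        )
    delta = c1 - c0
    if delta_convention == "unsigned":
        delta = np.abs(delta)
    y = cohort["nstemi"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("derivation cohort must contain both classes")
    return c0, delta, y


def _spec_from_combo(
    combo: Tuple[float, ...], marker: str, delta_convention: str, name: str
) -> AlgorithmSpec:
    a, b, dout, r0, din = combo
    return AlgorithmSpec(
        name=name,
        marker=marker,
        ruleout_single_0h=a,
        ruleout_paired_0h=b,
        ruleout_paired_delta=dout,
        rulein_0h=r0,
        rulein_delta=din,
        delta_convention=delta_convention,
        ruleout_single_requires_onset_gt=None,
    )


def derive_optimal(
    cohort: pd.DataFrame,
    targets: PerformanceTargets,
    grid: GridSpec,
    *,
    marker: str = "cmyc",
    delta_convention: str = "signed",
    objective: str = "efficacy",
    method: str = "auto",
    exhaustive_limit: int = 200_000,
) -> DerivationResult:
    """Search the grid for the best feasible rule set.

    ``objective="efficacy"`` (default) maximises the ruled-out + ruled-in
    count subject to the targets; ``"rule_out"`` maximises the rule-out
    count.  ``method`` is ``"exhaustive"``, ``"decomposed"`` or ``"auto"``
    (decomposed above ``exhaustive_limit`` combinations).  The audit trail
    lists every feasible valid combination with its summary statistics for
    the exhaustive search; the decomposed search's audit lists, for each
    feasible rule-out side, its best feasible rule-in completion (the set of
    candidates among which the optimum provably lies).
    """
    c0, delta, y = _extract_arrays(cohort, marker, delta_convention)
    if method == "auto":
        method = "exhaustive" if grid.n_combinations <= exhaustive_limit else "decomposed"
    if method == "exhaustive":
        best, audit, n_valid, infeas = _search_exhaustive(
            c0, delta, y, grid, targets, objective
        )
    elif method == "decomposed":
        best, audit, n_valid, infeas = _search_decomposed(
            c0, delta, y, grid, targets, objective
        )
    else:
        raise ValidationError(f"unknown search method {method!r}")

    if best is None:
        return DerivationResult(
            feasible=False,
            spec=None,
            summary=None,
            audit=audit,
            n_valid_combinations=n_valid,
            objective=objective,
            method=method,
            infeasibility=infeas,
        )
    spec = _spec_from_combo(best, marker, delta_convention, f"derived-{marker}-0/1h")
    summary = evaluate_threshold_set(cohort, spec)
    return DerivationResult(
        feasible=True,
        spec=spec,
        summary=summary,
        audit=audit,
        n_valid_combinations=n_valid,
        objective=objective,
        method=method,
    )


def _counts_for_combo(c0, delta, y, combo):
    a, b, dout, r0, din = combo
    ro = (c0 < a) | ((c0 >= a) & (c0 < b) & (delta < dout))
    ri = (c0 >= r0) | ((c0 >= a) & (c0 < r0) & (delta >= din))
    return (
        int(np.sum(ro & y)),
        int(np.sum(ro & ~y)),
        int(np.sum(ri & y)),
        int(np.sum(ri & ~y)),
    )


def _search_exhaustive(c0, delta, y, grid, targets, objective):
    positives = int(y.sum())
    n = len(y)
    best_key, best_combo = None, None
    relaxed_key, relaxed_combo, relaxed_row = None, None, None
    best_sens = best_npv = best_ppv = -np.inf
    rows = []
    n_valid = 0
    for combo in product(
        grid.ruleout_single_0h,
        grid.ruleout_paired_0h,
        grid.ruleout_paired_delta,
        grid.rulein_0h,
        grid.rulein_delta,
    ):
        a, b, dout, r0, din = combo
        if not (a <= b < r0 and dout <= din):
            continue
        n_valid += 1
        ro_pos, ro_neg, ri_pos, ri_neg = _counts_for_combo(c0, delta, y, combo)
        sens, npv, ppv, ok = _combo_feasibility(
            ro_pos, ro_neg, ri_pos, ri_neg, positives, targets
        )
        best_sens, best_npv, best_ppv = (
            max(best_sens, sens),
            max(best_npv, npv),
            max(best_ppv, ppv),
        )
        ro = ro_pos + ro_neg
        eff = ro + ri_pos + ri_neg
        key = _candidate_key(objective, eff, ro, combo)
        row = {
            **dict(zip(_KEY_COLS, combo)),
            "rule_out": ro,
            "rule_in": ri_pos + ri_neg,
            "efficacy": eff / n,
            "sensitivity": sens,
            "npv": npv,
            "ppv": ppv,
            "feasible": bool(ok),
        }
        if ok:
            rows.append(row)
            if best_key is None or key < best_key:
                best_key, best_combo = key, combo
        if relaxed_key is None or key < relaxed_key:
            relaxed_key, relaxed_combo, relaxed_row = key, combo, row
    audit = pd.DataFrame(rows, columns=list(_KEY_COLS) + [
        "rule_out", "rule_in", "efficacy", "sensitivity", "npv", "ppv", "feasible"
    ])
    infeas = None
    if best_combo is None:
        infeas = {
            "best_sensitivity": best_sens,
            "best_npv": best_npv,
            "best_ppv": best_ppv,
            "best_unconstrained": relaxed_row,
        }
    return best_combo, audit, n_valid, infeas


def _count_lt(sorted_vals: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    return np.searchsorted(sorted_vals, np.asarray(thresholds, dtype=float), side="left")


def _table_lt_lt(c0, delta, x_thresholds, d_thresholds):
    """T[i, j] = #{c0 < x_i and delta < d_j}."""
    out = np.empty((len(x_thresholds), len(d_thresholds)), dtype=np.int64)
    for j, d in enumerate(d_thresholds):
        sub = np.sort(c0[delta < d])
        out[:, j] = _count_lt(sub, x_thresholds)
    return out


def _table_lt_ge(c0, delta, x_thresholds, d_thresholds):
    """T[i, j] = #{c0 < x_i and delta >= d_j}."""
    out = np.empty((len(x_thresholds), len(d_thresholds)), dtype=np.int64)
    for j, d in enumerate(d_thresholds):
        sub = np.sort(c0[delta >= d])
        out[:, j] = _count_lt(sub, x_thresholds)
    return out


def _search_decomposed(c0, delta, y, grid, targets, objective):
    A = np.asarray(grid.ruleout_single_0h, dtype=float)
    B = np.asarray(grid.ruleout_paired_0h, dtype=float)
    DOUT = np.asarray(grid.ruleout_paired_delta, dtype=float)
    R0 = np.asarray(grid.rulein_0h, dtype=float)
    DIN = np.asarray(grid.rulein_delta, dtype=float)

    c0p, dp = c0[y], delta[y]
    c0n, dn = c0[~y], delta[~y]
    P, N = len(c0p), len(c0n)
    n = P + N
    sp, sn = np.sort(c0p), np.sort(c0n)

    # rule-out side: counts over (a, b, dout)
    P_lt_A, N_lt_A = _count_lt(sp, A), _count_lt(sn, A)
    Fp_B, Fn_B = _table_lt_lt(c0p, dp, B, DOUT), _table_lt_lt(c0n, dn, B, DOUT)
    Fp_A, Fn_A = _table_lt_lt(c0p, dp, A, DOUT), _table_lt_lt(c0n, dn, A, DOUT)
    ro_pos = P_lt_A[:, None, None] + Fp_B[None, :, :] - Fp_A[:, None, :]
    ro_neg = N_lt_A[:, None, None] + Fn_B[None, :, :] - Fn_A[:, None, :]

    # rule-in side: counts over (a, r0, din)
    P_ge_R = P - _count_lt(sp, R0)
    N_ge_R = N - _count_lt(sn, R0)
    Gp_R, Gn_R = _table_lt_ge(c0p, dp, R0, DIN), _table_lt_ge(c0n, dn, R0, DIN)
    Gp_A, Gn_A = _table_lt_ge(c0p, dp, A, DIN), _table_lt_ge(c0n, dn, A, DIN)
    ri_pos = P_ge_R[None, :, None] + Gp_R[None, :, :] - Gp_A[:, None, :]
    ri_neg = N_ge_R[None, :, None] + Gn_R[None, :, :] - Gn_A[:, None, :]

    sens = (P - ro_pos) / P
    npv = (ro_neg + 0.5) / (ro_pos + ro_neg + 1.0)
    ppv = (ri_pos + 0.5) / (ri_pos + ri_neg + 1.0)
    ro_ok = (sens >= targets.min_sensitivity) & (npv >= targets.min_npv)
    ri_ok = ppv >= targets.min_ppv
    valid_ab = B[None, :] >= A[:, None]  # a <= b

    ri_count = ri_pos + ri_neg
    ro_count = ro_pos + ro_neg

    # index maps for the cross-side constraints b < r0 and dout <= din
    i0_for_b = np.searchsorted(R0, B, side="right")  # first r with R0 > b
    j0_for_dout = np.searchsorted(DIN, DOUT, side="left")  # first k with DIN >= dout

    def best_ri_tables(mask):
        """For each a: DP table best[i, j] = best feasible rule-in choice with
        r >= i, k >= j; preference (max count, then max r0, then min din)."""
        nA, nR, nK = len(A), len(R0), len(DIN)
        bc = np.full((nA, nR + 1, nK + 1), -1, dtype=np.int64)
        br = np.full((nA, nR + 1, nK + 1), -1, dtype=np.int64)
        bk = np.full((nA, nR + 1, nK + 1), -1, dtype=np.int64)
        for ai in range(nA):
            for i in range(nR - 1, -1, -1):
                for j in range(nK - 1, -1, -1):
                    cnt, r_i, k_i = bc[ai, i + 1, j], br[ai, i + 1, j], bk[ai, i + 1, j]
                    c2, r2, k2 = bc[ai, i, j + 1], br[ai, i, j + 1], bk[ai, i, j + 1]
                    if (c2, r2, -k2) > (cnt, r_i, -k_i):
                        cnt, r_i, k_i = c2, r2, k2
                    if mask[ai, i, j]:
                        c3 = ri_count[ai, i, j]
                        if (c3, i, -j) > (cnt, r_i, -k_i):
                            cnt, r_i, k_i = c3, i, j
                    bc[ai, i, j], br[ai, i, j], bk[ai, i, j] = cnt, r_i, k_i
        return bc, br, bk

    def run(feasibility: bool):
        mask_ri = ri_ok if feasibility else np.ones_like(ri_ok, dtype=bool)
        mask_ro = ro_ok if feasibility else np.ones_like(ro_ok, dtype=bool)
        bc, br, bk = best_ri_tables(mask_ri)
        best_key, best_combo, best_counts = None, None, None
        rows = []
        nA, nB, nJ = len(A), len(B), len(DOUT)
        for ai in range(nA):
            for bi in range(nB):
                if not valid_ab[ai, bi]:
                    continue
                i0 = i0_for_b[bi]
                for ji in range(nJ):
                    if feasibility and not mask_ro[ai, bi, ji]:
                        continue
                    j0 = j0_for_dout[ji]
                    cnt = bc[ai, i0, j0]
                    if cnt < 0:
                        continue
                    ri_idx = (ai, br[ai, i0, j0], bk[ai, i0, j0])
                    combo = (
                        float(A[ai]),
                        float(B[bi]),
                        float(DOUT[ji]),
                        float(R0[ri_idx[1]]),
                        float(DIN[ri_idx[2]]),
                    )
                    ro = int(ro_count[ai, bi, ji])
                    eff = ro + int(cnt)
                    key = _candidate_key(objective, eff, ro, combo)
                    if feasibility:
                        rows.append(
                            {
                                **dict(zip(_KEY_COLS, combo)),
                                "rule_out": ro,
                                "rule_in": int(cnt),
                                "efficacy": eff / n,
                                "sensitivity": float(sens[ai, bi, ji]),
                                "npv": float(npv[ai, bi, ji]),
                                "ppv": float(ppv[ri_idx]),
                                "feasible": True,
                            }
                        )
                    if best_key is None or key < best_key:
                        best_key, best_combo = key, combo
                        best_counts = (ro, int(cnt))
        return best_combo, best_counts, rows

    # valid combos satisfy a <= b < r0 and dout <= din; the delta pair
    # factors from the concentration triple, hence the product
    n_din_ok = len(DIN) - j0_for_dout  # per dout: count of din >= dout
    n_r_ok = len(R0) - i0_for_b  # per b: count of r0 > b
    n_valid = int(np.sum(valid_ab * n_r_ok[None, :]) * np.sum(n_din_ok))

    best_combo, _, rows = run(feasibility=True)
    audit = pd.DataFrame(rows, columns=list(_KEY_COLS) + [
        "rule_out", "rule_in", "efficacy", "sensitivity", "npv", "ppv", "feasible"
    ])
    infeas = None
    if best_combo is None:
        relaxed_combo, relaxed_counts, _ = run(feasibility=False)
        relaxed_row = None
        if relaxed_combo is not None:
            ro, ri = relaxed_counts
            relaxed_row = {
                **dict(zip(_KEY_COLS, relaxed_combo)),
                "rule_out": ro,
                "rule_in": ri,
                "efficacy": (ro + ri) / n,
            }
        infeas = {
            "best_sensitivity": float(np.max(np.where(valid_ab[:, :, None], sens, -np.inf))),
            "best_npv": float(np.max(np.where(valid_ab[:, :, None], npv, -np.inf))),
            "best_ppv": float(np.max(ppv)),
            "best_unconstrained": relaxed_row,
        }
    return best_combo, audit, n_valid, infeas
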
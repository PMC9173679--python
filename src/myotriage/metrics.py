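"""Diagnostic-accuracy statistics for 0/1h triage algorithms.

Estimators follow common practice in rapid-triage validation studies:

* predictive values (NPV in the rule-out group, PPV in the rule-in group)
  are posterior means under a Jeffreys Beta(1/2, 1/2) prior, i.e.
  ``(x + 0.5) / (n + 1)``, with Beta-posterior credible intervals;
* sensitivity/specificity are raw proportions with Wilson score intervals
  (sensitivity is defined through rule-out safety, ``1 - FN/positives``
  with FN the ruled-out positives; specificity through rule-in accuracy);
* likelihood ratios are ``LR+ = sens/(1-spec)`` and ``LR- = (1-sens)/spec``
  with log-method intervals;
* efficacy is the proportion of patients triaged to either rule-out or
  rule-in;
* paired algorithms are compared with McNemar's test (sensitivity,
  specificity, triage proportions) and a cluster-robust generalized score
  test (predictive values), in which subjects positive under both
  algorithms form two-record clusters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.proportion import proportion_confint

from .models import MetricEstimate, TriageCategory, TriageConfusion, ValidationError

__all__ = [
    "jeffreys_proportion",
    "wilson_interval",
    "build_confusion",
    "group_metrics",
    "mcnemar_paired",
    "compare_predictive_values",
    "paired_pv_score_test",
    "performance_report",
    "fmt_percent",
    "PairedTestResult",
]


def jeffreys_proportion(
    successes: int, n: int, conf: float = 0.95, *, interval: str = "equal-tailed"
) -> MetricEstimate:
    """Bayes estimate of a proportion under the Jeffreys Beta(1/2,1/2) prior.

    Point estimate is the posterior mean ``(successes + 0.5)/(n + 1)``.  The
    default interval is the equal-tailed posterior credible interval (with
    the usual boundary convention: lower bound 0 when ``successes == 0``,
    upper bound 1 when ``successes == n``); ``interval="hpd"`` gives the
    highest-posterior-density interval instead, the variant that matches
    published one-sided-looking intervals such as "99.57% (98.88–100)".

    ``n == 0`` returns the prior mean 0.5 with the maximally wide interval,
    flagged degenerate.
    """
    if not 0 <= successes <= n:
        raise ValidationError(f"need 0 <= successes <= n, got {successes}/{n}")
    if n == 0:
        return MetricEstimate(0.5, 0.0, 1.0, "JEFFREYS", 0, defined=True, degenerate=True)
    value = (successes + 0.5) / (n + 1.0)
    a, b = successes + 0.5, n - successes + 0.5
    if interval == "equal-tailed":
        alpha = 1.0 - conf
        lower = 0.0 if successes == 0 else float(st.beta.ppf(alpha / 2, a, b))
        upper = 1.0 if successes == n else float(st.beta.ppf(1 - alpha / 2, a, b))
    elif interval == "hpd":
        lower, upper = _beta_hpd(a, b, conf)
    else:
        raise ValidationError(f"unknown interval type {interval!r}")
    return MetricEstimate(value, lower, upper, "JEFFREYS", n)


def _beta_hpd(a: float, b: float, conf: float) -> tuple[float, float]:
    """Shortest interval of posterior mass ``conf`` for a Beta(a, b)."""
    dist = st.beta(a, b)
    if a <= 1.0:  # mode at 0: one-sided from below
        return 0.0, float(dist.ppf(conf))
    if b <= 1.0:  # mode at 1: one-sided from above
        return float(dist.ppf(1.0 - conf)), 1.0
    from scipy.optimize import minimize_scalar

    def width(p_low: float) -> float:
        return dist.ppf(p_low + conf) - dist.ppf(p_low)

    res = minimize_scalar(width, bounds=(1e-10, 1.0 - conf - 1e-10), method="bounded")
    return float(dist.ppf(res.x)), float(dist.ppf(res.x + conf))


def wilson_interval(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValidationError("wilson_interval requires n >= 1")
    if not 0 <= successes <= n:
        raise ValidationError(f"need 0 <= successes <= n, got {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - conf, method="wilson")
    # the score interval touches the boundary exactly at degenerate counts;
    # snap float round-off so containment of the sample proportion holds
    lo = 0.0 if successes == 0 else max(float(lo), 0.0)
    hi = 1.0 if successes == n else min(float(hi), 1.0)
    return lo, hi


def _wilson_estimate(successes: int, n: int, conf: float) -> MetricEstimate:
    lo, hi = wilson_interval(successes, n, conf)
    return MetricEstimate(successes / n, lo, hi, "WILSON", n)


def build_confusion(triage_table: pd.DataFrame) -> TriageConfusion:
    """Tabulate a labelled triage table into per-category class counts."""
    if "nstemi" not in triage_table.columns:
        raise ValidationError("triage table has no 'nstemi' label column")
    counts = {}
    for cat, short in (
        (TriageCategory.RULE_OUT, "ruleout"),
        (TriageCategory.OBSERVE, "observe"),
        (TriageCategory.RULE_IN, "rulein"),
        (TriageCategory.INDETERMINATE, "indeterminate"),
    ):
        sub = triage_table[triage_table["category"] == cat.value]
        counts[f"{short}_pos"] = int((sub["nstemi"] == 1).sum())
        counts[f"{short}_neg"] = int((sub["nstemi"] == 0).sum())
    return TriageConfusion(**counts)


def _undefined(method: str) -> MetricEstimate:
    return MetricEstimate(
        float("nan"), float("nan"), float("nan"), method, 0, defined=False
    )


def _lr_interval(
    num_s: int, num_n: int, den_s: int, den_n: int, conf: float
) -> tuple[float, float]:
    """Log-method CI for a ratio of two proportions (num_s/num_n)/(den_s/den_n)."""
    if min(num_s, den_s) == 0:
        return float("nan"), float("nan")
    z = st.norm.ppf(0.5 + conf / 2.0)
    log_lr = math.log((num_s / num_n) / (den_s / den_n))
    se = math.sqrt(1 / num_s - 1 / num_n + 1 / den_s - 1 / den_n)
    return math.exp(log_lr - z * se), math.exp(log_lr + z * se)


def group_metrics(
    conf: TriageConfusion, conf_level: float = 0.95, *, pv_interval: str = "equal-tailed"
) -> Dict[str, MetricEstimate]:
    """All headline metrics of a triage confusion table.

    Rule-out safety: NPV (Jeffreys) and sensitivity (raw, Wilson CI) with
    sensitivity = 1 - ruled-out positives / positives.  Rule-in accuracy:
    PPV (Jeffreys) and specificity = 1 - ruled-in negatives / negatives.
    Efficacy is reported over all patients.  Metrics whose denominator is
    empty come back flagged undefined rather than as zero.
    """
    out: Dict[str, MetricEstimate] = {}
    P, N = conf.positives, conf.negatives

    if P > 0:
        tp_equiv = P - conf.ruleout_pos
        out["sensitivity"] = _wilson_estimate(tp_equiv, P, conf_level)
    else:
        out["sensitivity"] = _undefined("WILSON")
    if N > 0:
        tn_equiv = N - conf.rulein_neg
        out["specificity"] = _wilson_estimate(tn_equiv, N, conf_level)
    else:
        out["specificity"] = _undefined("WILSON")

    out["npv"] = (
        jeffreys_proportion(conf.ruleout_neg, conf.ruleout_total, conf_level, interval=pv_interval)
        if conf.ruleout_total > 0
        else _undefined("JEFFREYS")
    )
    out["ppv"] = (
        jeffreys_proportion(conf.rulein_pos, conf.rulein_total, conf_level, interval=pv_interval)
        if conf.rulein_total > 0
        else _undefined("JEFFREYS")
    )

    sens, spec = out["sensitivity"], out["specificity"]
    if sens.defined and spec.defined:
        fn, tp = conf.ruleout_pos, P - conf.ruleout_pos
        fp, tn = conf.rulein_neg, N - conf.rulein_neg
        if spec.value < 1.0:
            lo, hi = _lr_interval(tp, P, fp, N, conf_level)
            out["lr_plus"] = MetricEstimate(
                sens.value / (1.0 - spec.value), lo, hi, "PLUGIN", conf.n
            )
        else:
            out["lr_plus"] = MetricEstimate(
                float("inf"), float("nan"), float("nan"), "PLUGIN", conf.n, degenerate=True
            )
        if spec.value > 0.0:
            lo, hi = _lr_interval(fn, P, tn, N, conf_level)
            out["lr_minus"] = MetricEstimate(
                (1.0 - sens.value) / spec.value, lo, hi, "PLUGIN", conf.n
            )
        else:
            out["lr_minus"] = _undefined("PLUGIN")
    else:
        out["lr_plus"] = _undefined("PLUGIN")
        out["lr_minus"] = _undefined("PLUGIN")

    triaged = conf.ruleout_total + conf.rulein_total
    out["efficacy"] = (
        _wilson_estimate(triaged, conf.n, conf_level) if conf.n > 0 else _undefined("WILSON")
    )
    out["observe_prevalence"] = (
        _wilson_estimate(conf.observe_pos, conf.observe_total, conf_level)
        if conf.observe_total > 0
        else _undefined("WILSON")
    )
    return out


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False
    detail: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "degenerate": self.degenerate,
            **(self.detail or {}),
        }


def mcnemar_paired(
    correct_a: np.ndarray,
    correct_b: np.ndarray,
    *,
    continuity_correction: bool = False,
) -> PairedTestResult:
    """McNemar chi-square test on paired correct/incorrect indicators.

    ``b``/``c`` are the discordant-pair counts; the statistic is
    ``(b - c)^2 / (b + c)`` against chi-square(1), without continuity
    correction unless requested.  ``b + c == 0`` is degenerate: statistic 0,
    p = 1.
    """
    correct_a = np.asarray(correct_a, dtype=bool)
    correct_b = np.asarray(correct_b, dtype=bool)
    if correct_a.shape != correct_b.shape:
        raise ValidationError("paired arrays must have equal length")
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    detail = {"b": b, "c": c}
    if b + c == 0:
        return PairedTestResult(0.0, 1.0, degenerate=True, detail=detail)
    diff = abs(b - c)
    if continuity_correction:
        diff = max(diff - 1.0, 0.0)
    stat = diff**2 / (b + c)
    return PairedTestResult(float(stat), float(st.chi2.sf(stat, 1)), detail=detail)


def paired_pv_score_test(
    s_both: int,
    f_both: int,
    s_a: int,
    f_a: int,
    s_b: int,
    f_b: int,
):
    """Cluster-robust generalized score test for paired predictive values.

    Subjects in the relevant triage group (rule-in for PPV, rule-out for
    NPV) under algorithm A and/or B contribute one record per membership;
    ``s``/``f`` count outcome successes/failures among subjects in both
    groups, A's group only, and B's group only.  The score for the
    group-effect coefficient of a marginal identity-link model is evaluated
    at the pooled null estimate, with an empirical cluster-level variance:
    subjects in both groups form two-record clusters, which is how the
    pairing (and the test-membership weighting n_b/(n_a+n_b)) enters.

    Returns ``(z, p)`` with ``sign(z) = sign(PV_A - PV_B)``; all arguments
    may be numpy arrays (vectorised over simulation replicates).
    """
    s_both, f_both, s_a, f_a, s_b, f_b = (
        np.asarray(v, dtype=float) for v in (s_both, f_both, s_a, f_a, s_b, f_b)
    )
    n1 = s_both + f_both + s_a + f_a
    n2 = s_both + f_both + s_b + f_b
    total = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = (2 * s_both + s_a + s_b) / total
        xbar = n2 / total
        u = (s_both + s_b) - n2 * p0
        v = (
            s_both * ((1 - 2 * xbar) * (1 - p0)) ** 2
            + f_both * ((1 - 2 * xbar) * p0) ** 2
            + s_a * (xbar * (1 - p0)) ** 2
            + f_a * (xbar * p0) ** 2
            + s_b * ((1 - xbar) * (1 - p0)) ** 2
            + f_b * ((1 - xbar) * p0) ** 2
        )
        z = np.where(v > 0, -u / np.sqrt(np.where(v > 0, v, 1.0)), 0.0)
        p = np.where(v > 0, 2.0 * st.norm.sf(np.abs(z)), 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


_PV_GROUP = {"npv": TriageCategory.RULE_OUT.value, "ppv": TriageCategory.RULE_IN.value}


def compare_predictive_values(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    which: str = "npv",
) -> PairedTestResult:
    """Compare NPV or PPV of two algorithms on the same patients.

    Patients INDETERMINATE under either algorithm are excluded pairwise
    (their count is reported in the detail).  Raises when one algorithm's
    group is empty — a score test has no information there; a bootstrap
    comparison is the fallback.
    """
    which = which.lower()
    if which not in _PV_GROUP:
        raise ValidationError("which must be 'npv' or 'ppv'")
    merged = _align_pair(table_a, table_b)
    ind = TriageCategory.INDETERMINATE.value
    excluded = int(((merged["category_a"] == ind) | (merged["category_b"] == ind)).sum())
    merged = merged[(merged["category_a"] != ind) & (merged["category_b"] != ind)]

    group = _PV_GROUP[which]
    in_a = (merged["category_a"] == group).to_numpy()
    in_b = (merged["category_b"] == group).to_numpy()
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValidationError(
            f"{which.upper()} comparison impossible: at least one algorithm has an "
            f"empty {group} group; use a bootstrap comparison instead"
        )
    disease = merged["nstemi"].to_numpy().astype(bool)
    success = disease if which == "ppv" else ~disease

    cells = {
        "s_both": int(np.sum(in_a & in_b & success)),
        "f_both": int(np.sum(in_a & in_b & ~success)),
        "s_a": int(np.sum(in_a & ~in_b & success)),
        "f_a": int(np.sum(in_a & ~in_b & ~success)),
        "s_b": int(np.sum(~in_a & in_b & success)),
        "f_b": int(np.sum(~in_a & in_b & ~success)),
    }
    z, p = paired_pv_score_test(**cells)
    pv_a = (cells["s_both"] + cells["s_a"]) / in_a.sum()
    pv_b = (cells["s_both"] + cells["s_b"]) / in_b.sum()
    degenerate = z == 0.0 and p == 1.0
    return PairedTestResult(
        z,
        p,
        degenerate=degenerate,
        detail={
            **cells,
            f"{which}_a": pv_a,
            f"{which}_b": pv_b,
            "n_excluded_indeterminate": excluded,
        },
    )


def _align_pair(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two triage tables on patient id, insisting on identical cohorts."""
    for t, nm in ((table_a, "A"), (table_b, "B")):
        if "nstemi" not in t.columns:
            raise ValidationError(f"triage table {nm} has no 'nstemi' label column")
    merged = table_a.merge(
        table_b, on="id", how="outer", suffixes=("_a", "_b"), indicator=True
    )
    unmatched = merged.loc[merged["_merge"] != "both", "id"].tolist()
    if unmatched:
        raise ValidationError(f"cohorts do not match; unmatched ids: {unmatched[:10]}")
    if (merged["nstemi_a"] != merged["nstemi_b"]).any():
        raise ValidationError("labels disagree between the two triage tables")
    merged = merged.rename(columns={"nstemi_a": "nstemi"})
    return merged


def _paired_correctness(
    merged: pd.DataFrame, which: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-patient correctness indicators for McNemar comparisons."""
    disease = merged["nstemi"].to_numpy().astype(bool)
    ro = TriageCategory.RULE_OUT.value
    ri = TriageCategory.RULE_IN.value
    if which == "sensitivity":
        keep = disease
        correct_a = (merged["category_a"] != ro).to_numpy()
        correct_b = (merged["category_b"] != ro).to_numpy()
    elif which == "specificity":
        keep = ~disease
        correct_a = (merged["category_a"] != ri).to_numpy()
        correct_b = (merged["category_b"] != ri).to_numpy()
    else:
        raise ValidationError("which must be 'sensitivity' or 'specificity'")
    return correct_a[keep], correct_b[keep], keep


def compare_accuracy(
    table_a: pd.DataFrame, table_b: pd.DataFrame, which: str = "sensitivity"
) -> PairedTestResult:
    """McNemar comparison of sensitivity or specificity of two algorithms."""
    merged = _align_pair(table_a, table_b)
    ind = TriageCategory.INDETERMINATE.value
    merged = merged[(merged["category_a"] != ind) & (merged["category_b"] != ind)]
    a, b, _ = _paired_correctness(merged, which)
    return mcnemar_paired(a, b)


def compare_proportion(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    categories: Sequence[str],
    *,
    basis_0h_only: bool = False,
) -> PairedTestResult:
    """McNemar comparison of a paired triage-proportion (e.g. ruled-out)."""
    merged = _align_pair(table_a, table_b)

    def member(side: str) -> np.ndarray:
        m = merged[f"category_{side}"].isin(categories).to_numpy()
        if basis_0h_only:
            m &= (merged[f"basis_{side}"] == "0h").to_numpy()
        return m

    return mcnemar_paired(member("a"), member("b"))


def fmt_percent(count: int, total: int, decimals: int = 1) -> str:
    """Render a count as the percentage string a results table would print."""
    if total == 0:
        return "NA"
    return f"{round(100.0 * count / total, decimals):.{decimals}f}%" if decimals else f"{round(100.0 * count / total):d}%"


def performance_report(
    tables: Mapping[str, pd.DataFrame],
    conf_level: float = 0.95,
    *,
    reference: Optional[str] = None,
    pv_interval: str = "equal-tailed",
) -> dict:
    """Side-by-side performance of up to a few algorithms on a shared cohort.

    For each algorithm: NPV, sensitivity, PPV, specificity, LR+/-,
    proportions ruled-out / ruled-in / efficacy on the 0 h basis and after
    the full 0/1 h algorithm, observe-zone prevalence — all as integer
    counts plus rendered percentages (one decimal; LRs two decimals).  The
    first (or ``reference``) algorithm is compared pairwise against every
    other: McNemar for sensitivity/specificity and triage proportions, the
    generalized score test for NPV/PPV.
    """
    if not tables:
        raise ValidationError("no triage tables given")
    names = list(tables)
    reference = reference or names[0]
    if reference not in tables:
        raise ValidationError(f"reference {reference!r} not among algorithms")

    report: dict = {"algorithms": {}, "comparisons": {}, "reference": reference}
    n_cohort = None
    for name, table in tables.items():
        conf = build_confusion(table)
        if n_cohort is None:
            n_cohort = conf.n
            report["n"] = n_cohort
        metrics = group_metrics(conf, conf_level, pv_interval=pv_interval)
        is_cat = lambda cat: table["category"] == cat.value
        is_0h = table["basis"] == "0h"
        counts = {
            "rule_out": int(is_cat(TriageCategory.RULE_OUT).sum()),
            "rule_in": int(is_cat(TriageCategory.RULE_IN).sum()),
            "observe": int(is_cat(TriageCategory.OBSERVE).sum()),
            "indeterminate": int(is_cat(TriageCategory.INDETERMINATE).sum()),
            "rule_out_0h": int((is_cat(TriageCategory.RULE_OUT) & is_0h).sum()),
            "rule_in_0h": int((is_cat(TriageCategory.RULE_IN) & is_0h).sum()),
        }
        counts["efficacy"] = counts["rule_out"] + counts["rule_in"]
        counts["efficacy_0h"] = counts["rule_out_0h"] + counts["rule_in_0h"]
        entry = {
            "counts": counts,
            "metrics": {k: v.to_dict() for k, v in metrics.items()},
            "percent": {
                key: fmt_percent(counts[key], conf.n)
                for key in (
                    "rule_out",
                    "rule_in",
                    "observe",
                    "indeterminate",
                    "rule_out_0h",
                    "rule_in_0h",
                    "efficacy",
                    "efficacy_0h",
                )
            },
            "rendered": {
                "npv": _render_pct(metrics["npv"]),
                "sensitivity": _render_pct(metrics["sensitivity"]),
                "ppv": _render_pct(metrics["ppv"]),
                "specificity": _render_pct(metrics["specificity"]),
                "lr_plus": _render_lr(metrics["lr_plus"]),
                "lr_minus": _render_lr(metrics["lr_minus"]),
                "observe_prevalence": _render_pct(metrics["observe_prevalence"]),
            },
            "observe_prevalence_count": conf.observe_pos,
        }
        report["algorithms"][name] = entry

    ref_table = tables[reference]
    for name in names:
        if name == reference:
            continue
        other = tables[name]
        comp: dict = {}
        for which in ("sensitivity", "specificity"):
            comp[f"p_{which}"] = compare_accuracy(ref_table, other, which).to_dict()
        for which in ("npv", "ppv"):
            try:
                comp[f"p_{which}"] = compare_predictive_values(
                    ref_table, other, which
                ).to_dict()
            except ValidationError as exc:
                comp[f"p_{which}"] = {"error": str(exc)}
        comp["p_ruleout_0h"] = compare_proportion(
            ref_table, other, ["rule_out"], basis_0h_only=True
        ).to_dict()
        comp["p_ruleout"] = compare_proportion(ref_table, other, ["rule_out"]).to_dict()
        comp["p_rulein"] = compare_proportion(ref_table, other, ["rule_in"]).to_dict()
        comp["p_efficacy"] = compare_proportion(
            ref_table, other, ["rule_out", "rule_in"]
        ).to_dict()
        report["comparisons"][f"{reference}_vs_{name}"] = comp
    return report


def _render_pct(est: MetricEstimate, decimals: int = 2) -> str:
    if not est.defined or math.isnan(est.value):
        return "NA"
    v = round(100.0 * est.value, decimals)
    if math.isnan(est.lower):
        return f"{v:.{decimals}f}%"
    return (
        f"{v:.{decimals}f}% "
        f"({round(100.0 * est.lower, decimals):.{decimals}f}-"
        f"{round(100.0 * est.upper, decimals):.{decimals}f})"
    )


def _render_lr(est: MetricEstimate) -> str:
    if not est.defined or math.isnan(est.value):
        return "NA"
    if math.isinf(est.value):
        return "inf"
    if math.isnan(est.lower):
        return f"{est.value:.2f}"
    return f"{est.value:.2f} ({est.lower:.2f}-{est.upper:.2f})"


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a performance report into a tidy frame (one row per
    algorithm/quantity) for CSV export; percentages stay backed by counts."""
    rows = []
    for name, entry in report["algorithms"].items():
        for key, count in entry["counts"].items():
            rows.append(
                {
                    "algorithm": name,
                    "quantity": key,
                    "count": count,
                    "n": report["n"],
                    "rendered": entry["percent"].get(key, ""),
                }
            )
        for key, rendered in entry["rendered"].items():
            metric = entry["metrics"].get(key)
            rows.append(
                {
                    "algorithm": name,
                    "quantity": key,
                    "count": None,
                    "n": metric["n_effective"] if metric else None,
                    "rendered": rendered,
                    "value": metric["value"] if metric else None,
                }
            )
    return pd.DataFrame(rows)
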
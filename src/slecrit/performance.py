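"""Diagnostic-accuracy statistics against the expert reference standard.

Implements confusion-matrix metrics with exact (Clopper-Pearson) binomial
confidence intervals, ROC AUC by the Mann-Whitney estimator with DeLong
variance/CIs, per-subgroup evaluation, and the descriptive two-group tests
(Student's t, Pearson chi-square).

The AUC of a dichotomous rule equals (sensitivity + specificity) / 2; the
published-style AUCs in the high 0.97-0.99 range require the engines'
continuous scores, which is what :func:`evaluate` uses by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Cohort, subset

Z_TABLE_NOTE = None  # intentionally no magic constants; quantiles come from scipy


class MetricCI(NamedTuple):
    """Point estimate with confidence bounds, on the percent scale."""

    point: float
    low: float
    high: float


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class PerformanceReport:
    system: str
    subgroup: str
    cm: ConfusionMatrix
    sensitivity: Optional[MetricCI]
    specificity: Optional[MetricCI]
    ppv: Optional[MetricCI]
    npv: Optional[MetricCI]
    accuracy: Optional[MetricCI]
    auc: Optional[tuple[float, float, float]]
    score_type: str = "continuous"
    note: str = ""


def confusion(classifications: Sequence[bool], reference: Sequence[bool]) -> ConfusionMatrix:
    """Exact 2x2 counts of a binary classifier against the reference labels."""
    pred = np.asarray(classifications, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {ref.shape}")
    tp = int(np.sum(pred & ref))
    fn = int(np.sum(~pred & ref))
    tn = int(np.sum(~pred & ~ref))
    fp = int(np.sum(pred & ~ref))
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Beta-quantile) confidence interval for x successes in n trials.

    Returns proportions in [0, 1]; the lower bound is exactly 0 when x = 0
    and the upper bound exactly 1 when x = n.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n with n >= 1, got x={x}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _metric(x: int, n: int, level: float) -> Optional[MetricCI]:
    if n == 0:  # undefined ratio -> not available, never a silent zero
        return None
    lo, hi = clopper_pearson(x, n, level)
    return MetricCI(point=100.0 * x / n, low=100.0 * lo, high=100.0 * hi)


def metrics(cm: ConfusionMatrix, level: float = 0.95) -> dict[str, Optional[MetricCI]]:
    """Sensitivity/specificity/PPV/NPV/accuracy with exact binomial CIs (percent)."""
    if cm.n == 0:
        raise ValueError("all-zero confusion matrix")
    return {
        "sensitivity": _metric(cm.tp, cm.tp + cm.fn, level),
        "specificity": _metric(cm.tn, cm.tn + cm.fp, level),
        "ppv": _metric(cm.tp, cm.tp + cm.fp, level),
        "npv": _metric(cm.tn, cm.tn + cm.fn, level),
        "accuracy": _metric(cm.tp + cm.tn, cm.n, level),
    }


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks.

    V10[i] = fraction of controls scored below case i (ties count 1/2);
    V01[j] = fraction of cases scored above control j (ties count 1/2).
    """
    cases = scores[ref]
    controls = scores[~ref]
    n1, n0 = cases.size, controls.size
    allr = stats.rankdata(np.concatenate([cases, controls]), method="average")
    rc = stats.rankdata(cases, method="average")
    r0 = stats.rankdata(controls, method="average")
    v10 = (allr[:n1] - rc) / n0
    v01 = 1.0 - (allr[n1:] - r0) / n1
    return v10, v01


def delong_auc_variance(scores: Sequence[float], reference: Sequence[bool]) -> tuple[float, float]:
    """Mann-Whitney AUC and its DeLong variance estimate."""
    scores = np.asarray(scores, dtype=float)
    ref = np.asarray(reference, dtype=bool)
    if scores.shape != ref.shape:
        raise ValueError("length mismatch")
    n1 = int(ref.sum())
    n0 = int((~ref).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires at least one case and one control")
    v10, v01 = _placements(scores, ref)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if n1 > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n0 > 1 else 0.0
    return auc, s10 / n1 + s01 / n0


def roc_auc(scores: Sequence[float], reference: Sequence[bool],
            level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong Wald interval, truncated to [0, 1]."""
    auc, var = delong_auc_variance(scores, reference)
    z = float(stats.norm.ppf(0.5 + level / 2))
    half = z * np.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def roc_points(scores: Sequence[float], reference: Sequence[bool]) -> pd.DataFrame:
    """Empirical ROC curve (fpr, tpr, threshold) for export/plotting."""
    scores = np.asarray(scores, dtype=float)
    ref = np.asarray(reference, dtype=bool)
    order = np.argsort(-scores, kind="mergesort")
    s, r = scores[order], ref[order]
    thresholds = np.unique(s)[::-1]
    n1, n0 = ref.sum(), (~ref).sum()
    rows = [(0.0, 0.0, np.inf)]
    for t in thresholds:
        pred = scores >= t
        rows.append((np.sum(pred & ~ref) / n0, np.sum(pred & ref) / n1, t))
    return pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])


# ---------------------------------------------------------------------------
# Subgroup evaluation
# ---------------------------------------------------------------------------

def evaluate(cohort: Cohort, class_df: pd.DataFrame,
             subgroups: Iterable[str] = ("overall", "early_disease"),
             systems: Optional[Sequence[str]] = None,
             level: float = 0.95) -> list[PerformanceReport]:
    """One PerformanceReport per system x subgroup.

    ``class_df`` is the output of :func:`slecrit.engines.classify_all` (or a
    compatible frame indexed by patient_id with ``<system>_score`` and
    ``<system>_classified`` columns).  Subgroups defined on case attributes
    (early disease, duration strata, organ involvement) keep all controls;
    ``overall`` is the unfiltered cohort.  ROC uses the engine's continuous
    score.
    """
    from .engines import SYSTEMS
    systems = list(systems or SYSTEMS)
    missing = set(cohort.ids) - set(class_df.index)
    if missing:
        raise ValueError(f"classifications do not cover the cohort ({len(missing)} missing)")
    reports: list[PerformanceReport] = []
    for name in subgroups:
        sub = cohort if name == "overall" else subset(cohort, name)
        ids = sub.ids
        ref = np.array([r.reference_sle for r in sub.records], dtype=bool)
        for system in systems:
            if len(ids) == 0 or ref.all() or not ref.any():
                reports.append(PerformanceReport(
                    system=system, subgroup=name,
                    cm=ConfusionMatrix(0, 0, 0, 0) if len(ids) == 0 else confusion(
                        class_df.loc[ids, f"{system}_classified"].to_numpy(), ref),
                    sensitivity=None, specificity=None, ppv=None, npv=None,
                    accuracy=None, auc=None,
                    note="not computable: subgroup lacks a reference class"))
                continue
            pred = class_df.loc[ids, f"{system}_classified"].to_numpy(dtype=bool)
            scores = class_df.loc[ids, f"{system}_score"].to_numpy(dtype=float)
            cm = confusion(pred, ref)
            m = metrics(cm, level)
            reports.append(PerformanceReport(
                system=system, subgroup=name, cm=cm,
                sensitivity=m["sensitivity"], specificity=m["specificity"],
                ppv=m["ppv"], npv=m["npv"], accuracy=m["accuracy"],
                auc=roc_auc(scores, ref, level), score_type="continuous"))
    return reports


def reports_frame(reports: Iterable[PerformanceReport]) -> pd.DataFrame:
    """Long-format table of performance reports (percent metrics, 2 dp on render)."""
    rows = []
    for r in reports:
        row: dict = {"system": r.system, "subgroup": r.subgroup,
                     "tp": r.cm.tp, "fn": r.cm.fn, "tn": r.cm.tn, "fp": r.cm.fp,
                     "n_cases": r.cm.n_cases, "n_controls": r.cm.n_controls,
                     "note": r.note}
        for metric in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            mc = getattr(r, metric)
            row[metric] = mc.point if mc else np.nan
            row[f"{metric}_lo"] = mc.low if mc else np.nan
            row[f"{metric}_hi"] = mc.high if mc else np.nan
        if r.auc:
            row["auc"], row["auc_lo"], row["auc_hi"] = r.auc
        else:
            row["auc"] = row["auc_lo"] = row["auc_hi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Descriptive two-group comparisons
# ---------------------------------------------------------------------------

def compare_groups(cohort: Cohort, variable: str) -> dict:
    """Cases-vs-controls comparison of one variable.

    Continuous record attributes (``age_at_enrollment``, ``age_at_onset``,
    ``disease_duration``) are compared with Student's t-test (pooled
    variance); binary feature flags (``feature:<name>``) with the Pearson
    chi-square test on the 2x2 table, without continuity correction.
    """
    cases = [r for r in cohort.records if r.reference_sle]
    controls = [r for r in cohort.records if not r.reference_sle]
    if not cases or not controls:
        raise ValueError("both reference classes required")
    if variable.startswith("feature:"):
        fname = variable.split(":", 1)[1]
        a = sum(r.features.present(fname) for r in cases)
        b = sum(r.features.present(fname) for r in controls)
        table = np.array([[a, len(cases) - a], [b, len(controls) - b]])
        res = stats.chi2_contingency(table, correction=False)
        return {"test": "chi2", "statistic": float(res.statistic), "df": int(res.dof),
                "p": float(res.pvalue),
                "case_prevalence": a / len(cases), "control_prevalence": b / len(controls)}
    x = np.array([getattr(r, variable) for r in cases], dtype=float)
    y = np.array([getattr(r, variable) for r in controls], dtype=float)
    if np.var(x) + np.var(y) == 0:
        raise ValueError(f"zero-variance variable {variable!r}")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return {"test": "t", "statistic": float(t), "df": x.size + y.size - 2,
            "p": float(p), "case_mean": float(x.mean()), "control_mean": float(y.mean())}
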
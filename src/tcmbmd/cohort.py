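"""Cohort-level diagnostics: T-score classes, ROC/Youden, performance.

The reference standard is DXA: a subject's class is set by the lowest
T-score over the lumbar vertebrae (<= -2.5 osteoporosis, (-2.5, -1]
osteopenia, > -1 normal).  CT-derived vBMD is then evaluated as a
screening index via ROC analysis, with the convention that LOW vBMD is
disease-positive: a subject tests positive when vBMD <= threshold.

Two dichotomous endpoints are supported:

* ``osteoporosis``: positives are osteoporotic subjects only;
* ``osteopenia``: positives are all subjects with reduced bone mass
  (osteopenia plus osteoporosis) against normals.

Candidate ROC thresholds are midpoints between consecutive distinct
scores plus sentinels outside the observed range; AUC is the trapezoid
area, equal to the Mann-Whitney pairwise concordance with ties counted
one half.  The operating point is chosen by the Youden index
J = sensitivity + specificity - 1, ties broken toward higher
sensitivity and then lower threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "ROCResult",
    "DiagnosticPerformance",
    "classify_tscore",
    "endpoint_labels",
    "subject_scores",
    "roc_curve",
    "youden_threshold",
    "diagnostic_performance",
    "accuracy_from_sens_spec",
    "pearson_r",
    "age_regression",
    "pairwise_group_tests",
    "performance_table",
    "round_half_away",
]

GROUPS = ("normal", "osteopenia", "osteoporosis")
VERTEBRAE = ("L1", "L2", "L3", "L4")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed reports)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def classify_tscore(tscores: Iterable[float]) -> str:
    """Diagnostic class from per-vertebra T-scores (lowest governs)."""
    ts = [float(t) for t in tscores if np.isfinite(t)]
    if not ts:
        raise ValueError("at least one T-score is required")
    t = min(ts)
    if t <= -2.5:
        return "osteoporosis"
    if t <= -1.0:
        return "osteopenia"
    return "normal"


def endpoint_labels(groups: Sequence[str], endpoint: str) -> np.ndarray:
    """Boolean disease-positive labels for a dichotomous endpoint."""
    g = np.asarray(groups, dtype=object)
    if endpoint == "osteoporosis":
        return g == "osteoporosis"
    if endpoint == "osteopenia":
        return (g == "osteopenia") | (g == "osteoporosis")
    raise ValueError(f"unknown endpoint {endpoint!r}")


def subject_scores(cohort: pd.DataFrame, vertebra: str) -> np.ndarray:
    """Per-subject vBMD predictor: one vertebra or the L1-L4 mean.

    The 'average' classifier uses the per-subject mean vBMD over the
    available vertebrae, not an average of per-vertebra thresholds.
    """
    if vertebra == "average":
        cols = [f"vbmd_{v}" for v in VERTEBRAE if f"vbmd_{v}" in cohort.columns]
        return cohort[cols].mean(axis=1).to_numpy(dtype=float)
    col = f"vbmd_{vertebra}"
    if col not in cohort.columns:
        raise KeyError(col)
    return cohort[col].to_numpy(dtype=float)


@dataclass
class ROCResult:
    """ROC curve for a 'positive iff score <= threshold' test."""

    thresholds: np.ndarray = field(repr=False)  # ascending
    sensitivity: np.ndarray = field(repr=False)  # non-decreasing with threshold
    specificity: np.ndarray = field(repr=False)  # non-increasing with threshold
    auc: float = 0.0


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC over midpoint thresholds; trapezoid AUC.

    ``labels`` is True for diseased subjects; a subject tests positive
    when its score is <= threshold (low vBMD indicates disease).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matched 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    uniq = np.unique(s)
    span = max(uniq[-1] - uniq[0], 1.0)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 0.5 * span], mids, [uniq[-1] + 0.5 * span]))
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = s <= t
        sens[i] = (pred & y).sum() / n_pos
        spec[i] = (~pred & ~y).sum() / n_neg
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def youden_threshold(roc: ROCResult) -> tuple[float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity, then lower threshold.
    Returns (threshold, sensitivity, specificity).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, len(j)):
        if (
            j[i] > j[best] + 1e-12
            or (abs(j[i] - j[best]) <= 1e-12 and roc.sensitivity[i] > roc.sensitivity[best] + 1e-12)
        ):
            best = i
    return (
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
    )


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Operating-point metrics for one vertebra/endpoint."""

    endpoint: str
    vertebra: str
    threshold: float  # g/cm3, 'positive iff vBMD <= threshold'
    auc: float
    sensitivity: float  # %
    specificity: float  # %
    accuracy: float  # %


def diagnostic_performance(
    scores: Sequence[float],
    labels: Sequence[bool],
    threshold: float,
    endpoint: str = "",
    vertebra: str = "",
    auc: float = float("nan"),
) -> DiagnosticPerformance:
    """Confusion-matrix metrics at a fixed threshold, in percent.

    Percentages are rounded to one decimal, half away from zero, the
    convention of printed clinical tables.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    pred = s <= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    return DiagnosticPerformance(
        endpoint=endpoint,
        vertebra=vertebra,
        threshold=threshold,
        auc=auc,
        sensitivity=round_half_away(100.0 * tp / n_pos),
        specificity=round_half_away(100.0 * tn / n_neg),
        accuracy=round_half_away(100.0 * (tp + tn) / (n_pos + n_neg)),
    )


def accuracy_from_sens_spec(sens: float, spec: float, n_pos: int, n_neg: int) -> float:
    """Accuracy (%) implied by printed sensitivity/specificity and sizes.

    Reconstructs the integer confusion matrix by rounding TP and TN
    half away from zero, then reports accuracy to one decimal — a
    self-consistency check for published performance tables.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp = round_half_away(sens * n_pos / 100.0, 0)
    tn = round_half_away(spec * n_neg / 100.0, 0)
    return round_half_away(100.0 * (tp + tn) / (n_pos + n_neg))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def age_regression(
    ages: Sequence[float],
    bmd: Sequence[float],
    sex: Sequence[str],
) -> dict[str, dict[str, float]]:
    """Per-sex OLS of BMD on age: slope (units/year), intercept, stderr."""
    ages = np.asarray(ages, dtype=float)
    bmd = np.asarray(bmd, dtype=float)
    sex = np.asarray(sex, dtype=object)
    out: dict[str, dict[str, float]] = {}
    for s in sorted(set(sex)):
        m = sex == s
        if m.sum() < 3:
            raise ValueError(f"fewer than 3 subjects for sex {s!r}")
        if np.ptp(ages[m]) == 0:
            raise ValueError(f"degenerate age range for sex {s!r}")
        fit = stats.linregress(ages[m], bmd[m])
        out[str(s)] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "stderr": float(fit.stderr),
            "n": int(m.sum()),
        }
    return out


def pairwise_group_tests(cohort: pd.DataFrame, vertebra: str) -> pd.DataFrame:
    """Welch two-sample t-tests of vBMD between each pair of groups."""
    scores = subject_scores(cohort, vertebra)
    groups = cohort["group"].to_numpy(dtype=object)
    for g in GROUPS:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    rows = []
    for i in range(len(GROUPS)):
        for j in range(i + 1, len(GROUPS)):
            a, b = GROUPS[i], GROUPS[j]
            res = stats.ttest_ind(scores[groups == a], scores[groups == b], equal_var=False)
            rows.append({"group_a": a, "group_b": b, "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)


def performance_table(
    cohort: pd.DataFrame,
    endpoint: str,
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-vertebra (plus 'average') diagnostic performance.

    Without ``thresholds`` the Youden-optimal operating point is derived
    from the cohort itself (the experimental-cohort configuration); with
    fixed per-vertebra thresholds the cohort is scored at those points
    (the independent test-cohort configuration).
    """
    labels = endpoint_labels(cohort["group"].to_list(), endpoint)
    rows = []
    for vert in list(VERTEBRAE) + ["average"]:
        scores = subject_scores(cohort, vert)
        roc = roc_curve(scores, labels)
        if thresholds is None:
            thr, _, _ = youden_threshold(roc)
        else:
            thr = thresholds[vert]
        perf = diagnostic_performance(
            scores, labels, thr, endpoint=endpoint, vertebra=vert, auc=roc.auc
        )
        rows.append(
            {
                "endpoint": endpoint,
                "vertebra": vert,
                "threshold": round_half_away(thr, 3),
                "auc": roc.auc,
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "accuracy": perf.accuracy,
            }
        )
    return pd.DataFrame(rows)
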
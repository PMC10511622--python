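"""Diagnostic performance metrics and cohort statistics.

Confusion-count metrics (accuracy, balanced accuracy, precision, recall, F1)
are exact closed forms with rounding applied only at presentation (2 decimals,
half-up).  ROC curves use a threshold sweep with trapezoidal AUC — which
equals the Mann-Whitney pair-count statistic — and PR curves report average
precision (step interpolation) as the primary AUC-PR, with the trapezoidal
variant also exposed.  Cohort statistics cover Kolmogorov-Smirnov normality
(Lilliefors correction for estimated parameters), the Mann-Whitney U test,
medians/IQRs, and Pearson/Spearman correlations with the Evans qualitative
strength bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from sklearn.metrics import (auc, average_precision_score,
                             precision_recall_curve, roc_curve)

__all__ = ["MetricsReport", "confusion_metrics", "roc_pr", "cohort_stats",
           "correlation", "evans_band", "round_half_up", "report_from_scores"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    tn: int
    tp: int
    fn: int
    fp: int
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float | None = None
    auc_pr: float | None = None
    roc_points: np.ndarray | None = None   # (fpr, tpr) rows
    pr_points: np.ndarray | None = None    # (recall, precision) rows

    def rounded(self, ndigits: int = 2) -> dict:
        out = {"TN": self.tn, "TP": self.tp, "FN": self.fn, "FP": self.fp}
        for k in ("accuracy", "balanced_accuracy", "precision", "recall", "f1",
                  "auc_roc", "auc_pr"):
            v = getattr(self, k)
            out[k] = None if v is None else round_half_up(v, ndigits)
        return out


def confusion_metrics(tn: int, tp: int, fn: int, fp: int) -> MetricsReport:
    """Scalar metrics from confusion counts; exact closed forms."""
    counts = dict(tn=tn, tp=tp, fn=fn, fp=fp)
    for k, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count {k}={v}")
    total = tn + tp + fn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    nan = float("nan")
    recall = tp / (tp + fn) if tp + fn else nan
    precision = tp / (tp + fp) if tp + fp else nan
    tnr = tn / (tn + fp) if tn + fp else nan
    f1 = 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else nan
    return MetricsReport(
        tn=tn, tp=tp, fn=fn, fp=fp,
        accuracy=(tn + tp) / total,
        balanced_accuracy=(recall + tnr) / 2,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def roc_pr(scores, labels) -> dict:
    """ROC (trapezoidal AUC) and PR (average precision) curves."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    auc_pr_trap = float(auc(rec[::-1], prec[::-1]))
    return {
        "auc_roc": float(auc(fpr, tpr)),
        "auc_pr": float(average_precision_score(y, s)),
        "auc_pr_trapezoid": auc_pr_trap,
        "roc_points": np.column_stack([fpr, tpr]),
        "pr_points": np.column_stack([rec, prec]),
    }


def report_from_scores(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full report: confusion counts at a threshold plus ROC/PR AUCs."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pred = (s > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    rep = confusion_metrics(tn, tp, fn, fp)
    curves = roc_pr(s, y)
    rep.auc_roc = curves["auc_roc"]
    rep.auc_pr = curves["auc_pr"]
    rep.roc_points = curves["roc_points"]
    rep.pr_points = curves["pr_points"]
    return rep


def cohort_stats(values_a, values_b) -> dict:
    """Two-group comparison: KS normality per group, Mann-Whitney U, medians/IQR."""
    from statsmodels.stats.diagnostic import kstest_normal

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    ks_a = kstest_normal(a)
    ks_b = kstest_normal(b)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    out = {"ks_p_a": float(ks_a[1]), "ks_p_b": float(ks_b[1]),
           "mannwhitney_u": float(u), "mannwhitney_p": float(p)}
    for name, v in (("a", a), ("b", b)):
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        out[f"median_{name}"] = float(q2)
        out[f"iqr_{name}"] = (float(q1), float(q3))
    return out


_EVANS_BANDS = ((0.20, "very weak"), (0.40, "weak"), (0.60, "moderate"),
                (0.80, "strong"), (1.01, "very strong"))


def evans_band(r: float) -> str:
    """Qualitative strength of a correlation coefficient (Evans scale)."""
    a = abs(r)
    for hi, name in _EVANS_BANDS:
        if a < hi:
            return name
    return "very strong"


def correlation(x, y, method: str = "pearson") -> dict:
    """Pearson r or Spearman rho with two-sided p and the Evans band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"coefficient": float(r), "p": float(p), "band": evans_band(float(r))}
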
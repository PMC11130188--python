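"""Confusion-matrix statistics, exact binomial inference, and ROC/AUC.

Conventions: the pathogenic class is positive. Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/n, precision (PPV) =
TP/(TP+FP), NPV = TN/(TN+FN); the no-information rate (NIR) is the larger
reference-class proportion; Cohen's kappa uses expected agreement from the
marginals; F1 is the harmonic mean of PPV and sensitivity. Accuracy gets an
exact (Clopper-Pearson) confidence interval and a one-sided exact binomial
test against the NIR. Metrics with a zero denominator are reported as NaN
rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import DataError


@dataclass
class ConfusionStats:
    """Counts and (once completed) the derived metric panel."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    balanced_accuracy: float | None = None
    precision: float | None = None
    npv: float | None = None
    nir: float | None = None
    kappa: float | None = None
    f1: float | None = None
    accuracy_ci: tuple[float, float] | None = None
    p_acc_gt_nir: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "accuracy_ci_low": None if self.accuracy_ci is None else self.accuracy_ci[0],
            "accuracy_ci_high": None if self.accuracy_ci is None else self.accuracy_ci[1],
            "balanced_accuracy": self.balanced_accuracy,
            "no_information_rate": self.nir,
            "p_acc_gt_nir": self.p_acc_gt_nir,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.precision,
            "npv": self.npv,
            "kappa": self.kappa,
            "f1": self.f1,
        }
        return d


@dataclass
class ROCCurve:
    """Threshold sweep: classification is positive where score >= threshold."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero, matching hand-rounded published tables."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_matrix(true_labels, predicted_labels) -> ConfusionStats:
    """Count TP/FP/FN/TN with pathogenic (1) as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise DataError("true and predicted labels differ in length")
    values = set(np.unique(t)) | set(np.unique(p))
    if not values <= {0, 1}:
        raise DataError(f"labels must be binary 0/1, got {sorted(values)}")
    return ConfusionStats(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(cm: ConfusionStats, level: float = 0.95) -> ConfusionStats:
    """Fill the full derived metric panel from raw counts."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    n = tp + fp + fn + tn
    if n == 0:
        raise DataError("empty confusion matrix")
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    acc = (tp + tn) / n
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    nir = max(tp + fn, tn + fp) / n
    # expected agreement from the marginals
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((fn + tn) / n) * ((fp + tn) / n)
    p_e = p_yes + p_no
    kappa = (acc - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    f1 = (
        2.0 * ppv * sens / (ppv + sens)
        if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
        else float("nan")
    )
    ci = clopper_pearson_interval(tp + tn, n, level)
    p_nir = stats.binomtest(tp + tn, n, p=nir, alternative="greater").pvalue
    return ConfusionStats(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=(sens + spec) / 2.0,
        precision=ppv,
        npv=npv,
        nir=nir,
        kappa=kappa,
        f1=f1,
        accuracy_ci=ci,
        p_acc_gt_nir=float(p_nir),
    )


def clopper_pearson_interval(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not 0.0 < level < 1.0:
        raise DataError("confidence level must be in (0, 1)")
    if n < 1 or not 0 <= successes <= n:
        raise DataError(f"invalid counts: {successes} of {n}")
    alpha = 1.0 - level
    lower = (
        0.0
        if successes == 0
        else float(stats.beta.ppf(alpha / 2.0, successes, n - successes + 1))
    )
    upper = (
        1.0
        if successes == n
        else float(stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes))
    )
    return lower, upper


def nir_binomial_test(cm: ConfusionStats) -> float:
    """One-sided exact binomial p-value for accuracy exceeding the NIR."""
    n = cm.n
    if n == 0:
        raise DataError("empty confusion matrix")
    nir = max(cm.tp + cm.fn, cm.tn + cm.fp) / n
    return float(
        stats.binomtest(cm.tp + cm.tn, n, p=nir, alternative="greater").pvalue
    )


def roc_points(true_labels, scores) -> ROCCurve:
    """ROC curve by sweeping unique scores as thresholds (descending).

    Tied scores are grouped into a single operating point, so AUC by
    trapezoid equals the tie-corrected Mann-Whitney concordance
    probability. The curve is anchored at (0, 0) and (1, 1).
    """
    t = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise DataError("labels and scores differ in length")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    # cumulative counts at each distinct threshold (score >= threshold)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, t_sorted.size - 1]
    cum_tp = np.cumsum(t_sorted == 1)[cut]
    cum_fp = np.cumsum(t_sorted == 0)[cut]
    thresholds = np.r_[np.inf, s_sorted[cut]]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    curve = ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=0.0)
    curve.auc = auc_trapezoid(curve)
    return curve


def auc_trapezoid(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def evaluate_predictions(
    true_labels, predicted_labels, scores=None, level: float = 0.95
) -> dict:
    """Complete metric panel (and ROC/AUC when scores are given) as a dict."""
    cm = classification_metrics(
        confusion_matrix(true_labels, predicted_labels), level=level
    )
    out = cm.to_dict()
    if scores is not None:
        out["auc"] = roc_points(true_labels, scores).auc
    return out
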
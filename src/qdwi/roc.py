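"""ROC analysis with Youden-index thresholding and DeLong confidence bands.

Each diffusion parameter is evaluated as a single-threshold classifier for a
binary molecular question.  The empirical ROC curve is traced over all
observed values; the area under it is computed by the trapezoidal rule
(identical to the normalized Mann-Whitney statistic, with half-credit for
ties), the 95% CI by DeLong's structural-components variance estimator, and
the operating threshold by maximizing the Youden index J = sensitivity +
specificity - 1 (ties broken toward the smaller threshold).  The decision
rule is inclusive: predict positive when the value lies on the positive side
of the threshold or equals it.

The classifier direction (whether high or low values indicate the positive
class) is auto-oriented so that AUC >= 0.5, and recorded in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .voi import CohortTable

logger = logging.getLogger(__name__)

__all__ = ["ROCResult", "roc_analysis", "accuracy_from_rates",
           "stratified_performance", "roc_curve_points"]


@dataclass(frozen=True)
class ROCResult:
    """Diagnostic performance of one parameter for one binary question."""

    parameter: str
    question: str
    positive_label: str
    direction: str            # "higher-is-positive" | "lower-is-positive"
    auc: float
    ci_95: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(pos) * len(neg)))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float,
               level: float = 0.95) -> tuple[float, float]:
    """DeLong variance via placement values (structural components)."""
    m, n = len(pos), len(neg)
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / n
                    for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m
                    for q in neg])
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = np.sqrt(var)
    z = sps.norm.ppf(0.5 + level / 2)
    return (float(np.clip(auc - z * se, 0.0, 1.0)),
            float(np.clip(auc + z * se, 0.0, 1.0)))


def _confusion_at(values: np.ndarray, labels: np.ndarray, threshold: float,
                  higher_positive: bool) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) under the inclusive rule."""
    pred = values >= threshold if higher_positive else values <= threshold
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    sens = tp / n_pos if n_pos else np.nan
    spec = tn / n_neg if n_neg else np.nan
    return sens, spec, (tp + tn) / len(values)


def roc_analysis(values, labels, positive_label, parameter: str = "",
                 question: str = "") -> ROCResult:
    """Empirical ROC of ``values`` against binary ``labels``.

    ``labels`` may be any array; entries equal to ``positive_label`` form
    the positive class.  Both classes must be present with n >= 3 each.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive_label
    if is_pos.all() or not is_pos.any():
        raise ValueError("both classes must be present")
    if is_pos.sum() < 3 or (~is_pos).sum() < 3:
        raise ValueError("need at least 3 subjects per class")
    pos, neg = values[is_pos], values[~is_pos]
    auc = _rank_auc(pos, neg)
    higher_positive = auc >= 0.5
    if not higher_positive:
        auc = 1.0 - auc
        pos, neg = -pos, -neg
    ci = _delong_ci(pos, neg, auc)
    # Youden scan over all observed thresholds, ties toward the smaller one
    best_j, best_t = -np.inf, np.nan
    for t in np.unique(values):
        sens, spec, _ = _confusion_at(values, is_pos, t, higher_positive)
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and t < best_t):
            best_j, best_t = j, float(t)
    sens, spec, acc = _confusion_at(values, is_pos, best_t, higher_positive)
    return ROCResult(
        parameter=parameter, question=question,
        positive_label=str(positive_label),
        direction="higher-is-positive" if higher_positive
        else "lower-is-positive",
        auc=auc, ci_95=ci, threshold=best_t,
        sensitivity=sens, specificity=spec, accuracy=acc,
        n_pos=int(is_pos.sum()), n_neg=int((~is_pos).sum()))


def roc_curve_points(values, labels, positive_label,
                     higher_positive: bool = True) -> pd.DataFrame:
    """(threshold, FPR, TPR) table of the empirical ROC curve for plotting."""
    values = np.asarray(values, dtype=float)
    is_pos = np.asarray(labels) == positive_label
    rows = [{"threshold": np.inf if higher_positive else -np.inf,
             "fpr": 0.0, "tpr": 0.0}]
    ts = np.unique(values)
    for t in (ts[::-1] if higher_positive else ts):
        sens, spec, _ = _confusion_at(values, is_pos, float(t), higher_positive)
        rows.append({"threshold": float(t), "fpr": 1 - spec, "tpr": sens})
    return pd.DataFrame(rows)


def accuracy_from_rates(sensitivity: float, specificity: float,
                        n_pos: int, n_neg: int, tol: float = 0.005):
    """Reconstruct accuracy and the confusion matrix from printed rates.

    TP and TN are recovered as the integer counts nearest to rate x group
    size; a rate farther than ``tol`` from every integer count is rejected
    as inconsistent.  Returns ``(accuracy, confusion)`` where confusion is
    a dict with tp/fn/tn/fp.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    if abs(sensitivity - tp / n_pos) > tol:
        raise ValueError(f"sensitivity {sensitivity} inconsistent with any "
                         f"integer count out of {n_pos}")
    if abs(specificity - tn / n_neg) > tol:
        raise ValueError(f"specificity {specificity} inconsistent with any "
                         f"integer count out of {n_neg}")
    accuracy = (tp + tn) / (n_pos + n_neg)
    confusion = {"tp": tp, "fn": n_pos - tp, "tn": tn, "fp": n_neg - tn}
    return accuracy, confusion


def stratified_performance(cohort: CohortTable, stratum_flag: str,
                           parameter: str, fixed_threshold: float,
                           direction: str, question_column: str,
                           positive_label, subset: dict | None = None
                           ) -> pd.DataFrame:
    """Confusion metrics per stratum at an externally fixed threshold.

    The threshold is *not* re-optimized per stratum.  Strata missing one
    class report accuracy only (sensitivity/specificity NaN); empty strata
    are skipped with a log entry.
    """
    higher_positive = direction == "higher-is-positive"
    df = cohort.df
    if subset:
        for col, val in subset.items():
            df = df[df[col] == val]
    rows = []
    for stratum, sub in df.groupby(stratum_flag, dropna=False):
        sub = sub[np.isfinite(sub[parameter].to_numpy(dtype=float))]
        if len(sub) == 0:
            logger.warning("stratum %s=%r empty, skipped", stratum_flag,
                           stratum)
            continue
        values = sub[parameter].to_numpy(dtype=float)
        is_pos = (sub[question_column] == positive_label).to_numpy()
        sens, spec, acc = _confusion_at(values, is_pos, fixed_threshold,
                                        higher_positive)
        rows.append({stratum_flag: stratum, "n": len(sub),
                     "n_pos": int(is_pos.sum()),
                     "n_neg": int((~is_pos).sum()),
                     "sensitivity": sens, "specificity": spec,
                     "accuracy": acc})
    return pd.DataFrame(rows)
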
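"""Confusion-matrix metrics, ROC AUC and descriptive statistics.

Sensitivity (recall on the toxic class) and specificity are the primary
metrics for imbalanced toxicity endpoints; balanced accuracy summarises
the two.  AUC is threshold-independent and reported for comparability
with challenge leaderboards only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (e.g. no positives in the evaluated set)."""


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 1:
        a = a.ravel()
    if a.size and not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return a.astype(int)


def confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """Return (TP, FP, TN, FN) counts for binary labels/predictions."""
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fn = int(np.sum((t == 1) & (p == 0)))
    return tp, fp, tn, fn


def sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN); raises if the evaluated set has no positives."""
    if tp + fn < 1:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return tp / (tp + fn)


def specificity(tn: int, fp: int) -> float:
    """TN / (TN + FP); raises if the evaluated set has no negatives."""
    if tn + fp < 1:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return tn / (tn + fp)


def balanced_accuracy(sens: float, spec: float, harmonic: bool = False) -> float:
    """Mean of sensitivity and specificity.

    Arithmetic mean by default (the standard definition and the one used
    by the Tox21 challenge); ``harmonic=True`` gives the harmonic mean
    for sensitivity analysis.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity/specificity must lie in [0, 1]")
    if harmonic:
        if sens + spec == 0:
            return 0.0
        return 2.0 * sens * spec / (sens + spec)
    return (sens + spec) / 2.0


def auc(y_true, scores) -> float:
    """Area under the ROC curve by trapezoidal integration (tie-corrected)."""
    t = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float).ravel()
    if t.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    if len(np.unique(t)) < 2:
        raise UndefinedMetricError("AUC undefined: only one class present")
    return float(roc_auc_score(t, s))


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts plus the derived metrics for one model evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
        }


def evaluate(y_true, y_pred, scores=None, harmonic: bool = False) -> EvaluationResult:
    """Full evaluation from labels/predictions (and optional scores for AUC)."""
    tp, fp, tn, fn = confusion(y_true, y_pred)
    sens = sensitivity(tp, fn)
    spec = specificity(tn, fp)
    bacc = balanced_accuracy(sens, spec, harmonic=harmonic)
    a = auc(y_true, scores) if scores is not None else None
    return EvaluationResult(tp, fp, tn, fn, sens, spec, bacc, a)


_METRIC_FIELDS = ("sensitivity", "specificity", "balanced_accuracy", "auc")


def summarize_models(results: Sequence[EvaluationResult] | Iterable[dict]) -> pd.DataFrame:
    """Descriptive statistics over a collection of model evaluations.

    Each model is treated as an independent observation: for every metric
    the table reports mean, median, sample SD, SE = SD/sqrt(n) and the
    t-based 95% confidence interval.
    """
    rows = [r.to_dict() if isinstance(r, EvaluationResult) else dict(r) for r in results]
    if len(rows) < 2:
        raise ValueError("need at least 2 model results to summarize")
    df = pd.DataFrame(rows)
    out = []
    for metric in _METRIC_FIELDS:
        if metric not in df or df[metric].isna().all():
            continue
        vals = df[metric].dropna().to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        se = sd / np.sqrt(n)
        tcrit = float(stats.t.ppf(0.975, n - 1))
        out.append(
            {
                "metric": metric,
                "n": n,
                "mean": mean,
                "median": float(np.median(vals)),
                "sd": sd,
                "se": se,
                "ci_low": mean - tcrit * se,
                "ci_high": mean + tcrit * se,
            }
        )
    return pd.DataFrame(out)
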
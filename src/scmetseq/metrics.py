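"""Cohort-level diagnostic performance.

Confusion matrix of scMet-Seq calls against clinical truth, the four
standard rates (sensitivity, specificity, PPV, NPV — reported both as
exact fractions and as integer percentages, matching the study's
presentation), an empirical ROC with trapezoid AUC (equal to the
Mann-Whitney concordance probability, tie-corrected), and the
Mann-Whitney rank test for two-group comparisons of sCTC densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_curve as _roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    calls: Mapping[str, str],
    truth: Mapping[str, str],
) -> ConfusionMatrix:
    """Tally positive/negative calls against malignant/benign truth.

    Every called sample must have a truth label; the first missing one is
    named in the error.
    """
    tp = fp = tn = fn = 0
    for sample, call in calls.items():
        if sample not in truth:
            raise KeyError(f"no truth label for called sample {sample!r}")
        malignant = truth[sample] == "malignant"
        positive = call == "positive"
        if positive and malignant:
            tp += 1
        elif positive:
            fp += 1
        elif malignant:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def diagnostic_metrics(cm: ConfusionMatrix) -> dict:
    """Sensitivity, specificity, PPV, NPV as fractions and integer percent.

    Fractions are exact; the ``*_pct`` entries round half up to 0 decimals
    (78.87% -> 79).  A rate with a zero denominator is reported as None.
    """
    rates = {
        "sensitivity": _rate(cm.tp, cm.tp + cm.fn),
        "specificity": _rate(cm.tn, cm.tn + cm.fp),
        "ppv": _rate(cm.tp, cm.tp + cm.fp),
        "npv": _rate(cm.tn, cm.tn + cm.fn),
    }
    out = dict(rates)
    for name, value in rates.items():
        out[f"{name}_pct"] = None if value is None else int(math.floor(100 * value + 0.5))
    return out


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[bool | int]) -> RocResult:
    """Empirical ROC over all unique score thresholds, trapezoid AUC.

    With ties handled by the trapezoid rule, the AUC equals the
    Mann-Whitney concordance probability
    P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg).
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def rank_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation null when both groups have n <= 10 and the data are
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
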
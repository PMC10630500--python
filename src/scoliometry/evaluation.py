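"""Statistical evaluation: Spearman correlation, ROC with Youden-index cutoff
selection, and ordinary least-squares regression.

The ROC cutoff is chosen among the observed score values (decision rule:
positive iff score >= cutoff) by maximizing the Youden index
J = sensitivity + specificity - 1; when several cutoffs tie on J the policy
breaks the tie, favoring sensitivity for the moderate-scoliosis task and
specificity for the severe-scoliosis task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

MAX_SENSITIVITY = "max-sensitivity"
MAX_SPECIFICITY = "max-specificity"


class DegenerateLabelsError(ValueError):
    """ROC needs both a positive and a negative class."""


@dataclass(frozen=True)
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    policy: str


def spearman(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Spearman rank correlation with averaged ties; p from the
    t-approximation with n - 2 degrees of freedom."""
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError(f"need >= 3 (a, b) pairs; got shape {arr.shape}")
    a, b = arr[:, 0], arr[:, 1]
    if np.ptp(stats.rankdata(a)) == 0 or np.ptp(stats.rankdata(b)) == 0:
        raise ValueError("undefined correlation: zero rank variance")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def _rates_at_cutoff(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> tuple[float, float, float, float, float]:
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / labels.size
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    return sens, spec, acc, ppv, npv


def trapezoidal_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve.

    Equivalent to the pairwise-concordance probability with ties counted 1/2.
    """
    # Sweep cutoffs from +inf down through the unique scores: (FPR, TPR)
    # starts at (0, 0) and ends at (1, 1).
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_labels == 1)[distinct]
    fps = np.cumsum(sorted_labels == 0)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return float(np.trapezoid(tpr, fpr))


def roc_with_youden(
    scores: Sequence[float], labels: Sequence[int], policy: str = MAX_SENSITIVITY
) -> RocResult:
    """ROC analysis with Youden-index cutoff selection and a tie policy."""
    if policy not in (MAX_SENSITIVITY, MAX_SPECIFICITY):
        raise ValueError(f"unknown policy {policy!r}")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not ((labels == 1).any() and (labels == 0).any()):
        raise DegenerateLabelsError("both classes must be present")

    auc = trapezoidal_auc(scores, labels)

    best: tuple[float, float, RocResult] | None = None
    for cutoff in np.unique(scores):
        sens, spec, acc, ppv, npv = _rates_at_cutoff(scores, labels, cutoff)
        j = sens + spec - 1.0
        tie_key = sens if policy == MAX_SENSITIVITY else spec
        if best is None or (j, tie_key) > (best[0], best[1]):
            best = (
                j,
                tie_key,
                RocResult(auc, float(cutoff), sens, spec, acc, ppv, npv, policy),
            )
    assert best is not None
    return best[2]


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares of y on x; returns (intercept, slope)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be 1-D, equal length, n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("singular fit: x is constant")
    result = stats.linregress(x, y)
    return float(result.intercept), float(result.slope)
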
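"""ROC analysis, Youden-optimal thresholds, and confusion-matrix metrics.

Thresholds are placed at midpoints between adjacent distinct observed
scores (plus sentinels below the minimum and above the maximum), which is
why integer sum scores yield half-integer cutoffs. A participant is
predicted "case" iff score > threshold; the direction is auto-detected
from group means and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float
    flipped: bool = False


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def _auc_mann_whitney(scores: np.ndarray, is_case: np.ndarray) -> float:
    """Tie-corrected rank AUC: P(case > comparison) + 0.5 P(tie)."""
    ranks = sps.rankdata(scores)
    n1 = int(is_case.sum())
    n0 = scores.size - n1
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc(
    scores: np.ndarray,
    labels: np.ndarray,
    case_label="case",
    direction: str = "auto",
) -> RocResult:
    """ROC curve over the midpoint threshold grid with Mann-Whitney AUC.

    Parameters
    ----------
    scores : score per participant.
    labels : group label per participant; ``case_label`` marks cases.
    direction : "auto" flips scores when the case group scores lower on
        average; "higher" asserts cases score higher, "lower" the reverse.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == case_label
    if not is_case.any() or is_case.all():
        raise ValueError("both classes must be present")
    flipped = False
    if direction == "auto":
        flipped = scores[is_case].mean() < scores[~is_case].mean()
    elif direction == "lower":
        flipped = True
    elif direction != "higher":
        raise ValueError("direction must be auto, higher or lower")
    work = -scores if flipped else scores

    uniq = np.unique(work)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    grid = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    case_scores = work[is_case]
    comp_scores = work[~is_case]
    sens = (case_scores[None, :] > grid[:, None]).mean(axis=1)
    spec = (comp_scores[None, :] <= grid[:, None]).mean(axis=1)

    auc = _auc_mann_whitney(work, is_case)
    j = sens + spec - 1.0
    best = _youden_index(grid, sens, spec)
    return RocResult(
        thresholds=grid,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=float(grid[best]),
        youden_j=float(j[best]),
        flipped=flipped,
    )


def _youden_index(grid: np.ndarray, sens: np.ndarray, spec: np.ndarray) -> int:
    """Argmax of J; ties broken toward balanced sens/spec, then lower threshold."""
    j = sens + spec - 1.0
    jmax = j.max()
    tied = np.flatnonzero(j >= jmax - 1e-12)
    balance = np.abs(sens[tied] - spec[tied])
    best_balance = balance.min()
    tied = tied[balance <= best_balance + 1e-12]
    return int(tied[0])


def youden_optimal(result: RocResult) -> tuple[float, float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Returns (threshold, sensitivity, specificity, accuracy), where accuracy
    assumes the empirical class mix of the ROC input (balanced weighting of
    sens/spec is recovered when group sizes are equal).
    """
    i = _youden_index(result.thresholds, result.sensitivity, result.specificity)
    sens = float(result.sensitivity[i])
    spec = float(result.specificity[i])
    # accuracy at equal weighting; exact counts come from confusion_metrics
    return float(result.thresholds[i]), sens, spec, (sens + spec) / 2.0


def classify_at(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    case_label="case",
    flipped: bool = False,
) -> ConfusionCounts:
    """Confusion counts for the rule 'case iff score > threshold'."""
    scores = np.asarray(scores, dtype=float)
    work = -scores if flipped else scores
    is_case = np.asarray(labels) == case_label
    pred = work > threshold
    return ConfusionCounts(
        tp=int((pred & is_case).sum()),
        fp=int((pred & ~is_case).sum()),
        tn=int((~pred & ~is_case).sum()),
        fn=int((~pred & is_case).sum()),
    )


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from raw counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be non-empty")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
    return float(sens), float(spec), float(acc)
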
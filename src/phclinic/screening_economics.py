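"""Test-skipping screening economics.

A risk predictor lets a screening programme measure an expensive test
(here: blood glucose) only in high-risk subjects. This module turns
per-subject risk scores into an ROC curve, selects an operating threshold
either by Youden's index J = TPR − FPR (equivalently, minimising the
balanced error rate 1 − TPR + FPR) or by a budget cap on the number of
tests, and converts the chosen operating point into expected confusion
counts, tests skipped, oversights (missed positives) and cost per
subject.

Expected counts are rounded half-away-from-zero on the *skipped* cells
(true negatives and false negatives), with true/false positives obtained
by differencing so that class totals are conserved exactly — the
convention under which the published worked example (462 positives,
15,243 negatives, TPR 87.6%, FPR 5.9%) yields 14,344 skipped tests, 57
oversights, and 1304 tests performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "RocCurve",
    "OperatingPoint",
    "ScreeningPlan",
    "roc_curve",
    "balanced_error_rate",
    "youden_threshold",
    "budget_threshold",
    "expected_plan",
    "savings_ratio",
]


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    tpr: float
    fpr: float

    @property
    def youden_j(self) -> float:
        return self.tpr - self.fpr


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points, ordered by descending threshold.

    Tied scores flip together, so there is one point per distinct score
    value plus the (0, 0) anchor at threshold +inf; the final point
    (lowest threshold) is always (1, 1).
    """

    thresholds: np.ndarray  # descending; thresholds[0] = +inf
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def auc(self) -> float:
        """Area under the curve, trapezoid rule."""
        return float(np.trapezoid(self.tpr, self.fpr))

    def points(self) -> list[OperatingPoint]:
        return [
            OperatingPoint(float(t), float(s), float(f))
            for t, s, f in zip(self.thresholds, self.tpr, self.fpr)
        ]


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Build the ROC curve of a score vector against boolean labels.

    A subject is flagged positive when ``score >= threshold``. Both
    classes must be present.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build an ROC curve")
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    thr = thr.astype(float)
    thr[0] = math.inf  # sklearn uses max(score)+1 as the first anchor
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, n_pos=n_pos, n_neg=n_neg)


def balanced_error_rate(tpr: float, fpr: float) -> float:
    """Balanced error rate 1 − TPR + FPR (0 for a perfect classifier)."""
    if not (0.0 <= tpr <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ValueError("tpr and fpr must lie in [0, 1]")
    return 1.0 - tpr + fpr


def youden_threshold(roc: RocCurve) -> OperatingPoint:
    """Operating point maximizing Youden's J = TPR − FPR.

    J is also the (scaled) distance from the 45° chance line, and the
    maximizer of J minimizes the balanced error rate. Ties are broken
    toward the smaller FPR (the more conservative, fewer-tests point).
    """
    j = roc.tpr - roc.fpr
    best = j.max()
    candidates = np.flatnonzero(j >= best - 1e-12)
    idx = candidates[np.argmin(roc.fpr[candidates])]
    return OperatingPoint(float(roc.thresholds[idx]), float(roc.tpr[idx]), float(roc.fpr[idx]))


def budget_threshold(
    scores: Sequence[float], max_tests: int
) -> tuple[float, int]:
    """Threshold that tests the highest-risk subjects within a budget.

    Sorts the risk scores in descending order and takes the
    ``max_tests``-th score as the threshold; every subject with
    ``score >= threshold`` is flagged for testing. When ties at the
    threshold would push the flagged count over the budget, the whole tie
    group is excluded, so the realized count never exceeds ``max_tests``.

    Returns ``(threshold, realized_count)``; ``max_tests >= n`` flags
    everyone and ``max_tests = 0`` nobody (threshold +inf).
    """
    if max_tests < 0:
        raise ValueError("max_tests must be >= 0")
    s = np.asarray(scores, dtype=float)
    if max_tests == 0 or s.size == 0:
        return math.inf, 0
    if max_tests >= s.size:
        return float(s.min()), int(s.size)
    uniq, counts = np.unique(s, return_counts=True)  # ascending
    flagged = np.cumsum(counts[::-1])  # flagged count at each descending threshold
    thresholds = uniq[::-1]
    ok = np.flatnonzero(flagged <= max_tests)
    if ok.size == 0:
        return math.inf, 0
    pick = ok[-1]  # lowest admissible threshold
    return float(thresholds[pick]), int(flagged[pick])


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScreeningPlan:
    """Expected outcome of screening at one operating point."""

    threshold: Optional[float]
    tpr: float
    fpr: float
    tp: int
    fp: int
    tn: int
    fn: int
    cost_per_test: Optional[float] = None

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def tests_performed(self) -> int:
        return self.tp + self.fp

    @property
    def tests_skipped(self) -> int:
        return self.tn + self.fn

    @property
    def oversights(self) -> int:
        """Positive subjects whose test is skipped (false negatives)."""
        return self.fn

    @property
    def cost_total(self) -> Optional[float]:
        if self.cost_per_test is None:
            return None
        return self.tests_performed * self.cost_per_test

    @property
    def cost_per_subject(self) -> Optional[float]:
        total = self.cost_total
        return None if total is None else total / self.n_total

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "tests_performed": self.tests_performed,
            "tests_skipped": self.tests_skipped,
            "oversights": self.oversights,
            "balanced_error_rate": balanced_error_rate(self.tpr, self.fpr),
            "cost_per_test": self.cost_per_test,
            "cost_total": self.cost_total,
            "cost_per_subject": self.cost_per_subject,
        }


def expected_plan(
    n_pos: int,
    n_neg: int,
    tpr: float,
    fpr: float,
    cost_per_test: Optional[float] = None,
    threshold: Optional[float] = None,
) -> ScreeningPlan:
    """Expected confusion counts and costs at an operating point.

    The skipped cells are rounded half-away-from-zero —
    ``tn = round(n_neg·(1−fpr))``, ``fn = round(n_pos·(1−tpr))`` — and the
    tested cells obtained by differencing, so ``tp+fn = n_pos`` and
    ``fp+tn = n_neg`` hold exactly.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("class counts must be >= 0")
    if not (0.0 <= tpr <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ValueError("tpr and fpr must lie in [0, 1]")
    fn = _round_half_away(n_pos * (1.0 - tpr))
    tn = _round_half_away(n_neg * (1.0 - fpr))
    return ScreeningPlan(
        threshold=threshold,
        tpr=tpr,
        fpr=fpr,
        tp=n_pos - fn,
        fp=n_neg - tn,
        tn=tn,
        fn=fn,
        cost_per_test=cost_per_test,
    )


def savings_ratio(plan: ScreeningPlan, n_total: Optional[int] = None) -> float:
    """Cost of the plan relative to testing everyone (fraction in [0, 1])."""
    if n_total is None:
        n_total = plan.n_total
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return plan.tests_performed / n_total
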
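"""Imbalance-aware precision/recall machinery.

On heavily imbalanced data (one positive per 999 negatives, say) accuracy
and ROC curves are uninformative; precision-recall curves and the area
under them (AUPRC) are the right currency, because the random-scorer
baseline equals the class prevalence. Conventions used throughout:

* a call is positive iff score >= threshold;
* precision is defined as 0 when no positives are called;
* AUPRC is the step-function average precision, sum((R_i - R_{i-1}) * P_i)
  over descending distinct thresholds — items sharing a score enter the
  confusion counts together, so ties are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRPoint",
    "PRCurve",
    "precision_recall_at",
    "pr_curve",
    "f1_vs_threshold",
    "compare_methods",
    "DEFAULT_F1_GRID",
]

DEFAULT_F1_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class PRCurve:
    points: tuple[PRPoint, ...]
    auprc: float


def _f1(precision: float, recall: float) -> float:
    denom = precision + recall
    return 2.0 * precision * recall / denom if denom > 0 else 0.0


def _check_inputs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError(
            f"scores and labels must be equal-length 1-D, got {s.shape} vs {y.shape}"
        )
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return s, y


def precision_recall_at(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> PRPoint:
    """Precision/recall/F1 of the rule score >= threshold."""
    s, y = _check_inputs(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("labels contain no positives; recall is undefined")
    called = s >= threshold
    tp = int((called & (y == 1)).sum())
    fp = int((called & (y == 0)).sum())
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / n_pos
    return PRPoint(threshold, precision, recall, _f1(precision, recall))


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> PRCurve:
    """Full precision-recall curve over all distinct score thresholds.

    AUPRC is the average-precision step sum; recall is non-decreasing along
    the returned points (thresholds descend).
    """
    s, y = _check_inputs(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("pr_curve requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices where a run of tied scores ends
    boundaries = np.nonzero(np.diff(s_sorted))[0]
    last = np.concatenate([boundaries, [len(s_sorted) - 1]])
    tp_cum = np.cumsum(y_sorted)[last]
    calls = last + 1
    precision = tp_cum / calls
    recall = tp_cum / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    auprc = float(np.sum((recall - prev_recall) * precision))
    points = tuple(
        PRPoint(float(s_sorted[i]), float(p), float(r), _f1(float(p), float(r)))
        for i, p, r in zip(last, precision, recall)
    )
    return PRCurve(points, auprc)


def f1_vs_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    grid: Sequence[float] | None = None,
) -> tuple[list[PRPoint], float]:
    """F1 at every grid threshold plus the F1-maximizing threshold.

    Ties on F1 are resolved toward the smallest threshold. The default grid
    is 0.00..1.00 in steps of 0.01, the resolution used to propose the
    sensitive/precise operating points.
    """
    if grid is None:
        grid = DEFAULT_F1_GRID
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    points = [precision_recall_at(scores, labels, t) for t in grid]
    best = max(range(len(points)), key=lambda i: (points[i].f1, -grid[i]))
    return points, float(grid[best])


def compare_methods(
    score_tables: Mapping[str, Sequence[float]],
    labels: Sequence[int],
    static_methods: Mapping[str, Sequence[bool]] | None = None,
) -> pd.DataFrame:
    """Multi-method comparison table: AUPRC for scored methods,
    precision/recall for static (boolean) ones.

    All score/call lists must align item-for-item with ``labels``.
    """
    y = np.asarray(labels, dtype=int)
    rows = []
    for name, scores in score_tables.items():
        if len(scores) != len(y):
            raise ValueError(f"method {name!r}: {len(scores)} scores vs {len(y)} labels")
        curve = pr_curve(scores, y)
        rows.append(
            {"method": name, "kind": "scored", "auprc": curve.auprc,
             "precision": np.nan, "recall": np.nan}
        )
    for name, calls in (static_methods or {}).items():
        if len(calls) != len(y):
            raise ValueError(f"method {name!r}: {len(calls)} calls vs {len(y)} labels")
        point = precision_recall_at(np.asarray(calls, dtype=float), y, 0.5)
        rows.append(
            {"method": name, "kind": "static", "auprc": np.nan,
             "precision": point.precision, "recall": point.recall}
        )
    return pd.DataFrame(rows, columns=["method", "kind", "auprc", "precision", "recall"])
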
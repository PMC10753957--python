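"""AP-75 with instance size as a surrogate confidence score.

Bottom-up instance decoders produce no per-instance detection confidence, so
predictions are ranked by voxel count (largest first) before the standard
interpolated-precision average is taken:

    p_interp(r) = max_{r' >= r} p(r'),
    AP = (1/11) * sum over r in {0.0, 0.1, ..., 1.0} of p_interp(r),

with greedy rank-order matching: each prediction claims its highest-IoU
still-unclaimed GT instance if that IoU reaches the threshold (0.75 for
AP-75), else it is a false positive.  Size-as-confidence biases the metric —
a small GT merged into a larger prediction silently becomes an FN — which is
one reason the Hungarian accuracy score exists; both are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .overlap import OverlapTable
from .volumes import InstanceIndex

RECALL_LEVELS = np.linspace(0.0, 1.0, 11)


@dataclass
class RankedPredictions:
    """Prediction ids ordered by descending size; ties by ascending id."""

    order: list[int]
    confidence: dict[int, int]


@dataclass
class PRCurve:
    """Cumulative (recall, precision) points along the confidence ranking."""

    points: list[tuple[float, float]]
    n_gt: int

    def interp_precision(self, r: float) -> float:
        """Eq.-style interpolated precision: max precision at recall >= r."""
        best = 0.0
        for rr, pp in self.points:
            if rr >= r and pp > best:
                best = pp
        return best


def rank_by_size(index: InstanceIndex) -> RankedPredictions:
    order = sorted(index.ids, key=lambda i: (-index.sizes[i], i))
    return RankedPredictions(order=order, confidence=dict(index.sizes))


def pr_curve(
    ranked: RankedPredictions, table: OverlapTable, T: float = 0.75
) -> PRCurve:
    """Greedy rank-order matching and the resulting cumulative PR points.

    Each prediction, in confidence order, matches the highest-IoU GT not yet
    claimed when that IoU >= T (ties broken toward the lowest gt id); else it
    counts as FP.  One PR point is appended per prediction.
    """
    if not (0.0 < T <= 1.0):
        raise ValueError(f"IoU threshold must be in (0, 1], got {T}")
    n_gt = len(table.gt_sizes)
    claimed: set[int] = set()
    tp = fp = 0
    points: list[tuple[float, float]] = []
    for p in ranked.order:
        best_g, best_iou = None, 0.0
        for g in table.gt_sizes:
            if g in claimed:
                continue
            v = table.iou(g, p)
            if v > best_iou or (v == best_iou and v > 0 and (best_g is None or g < best_g)):
                best_g, best_iou = g, v
        if best_g is not None and best_iou >= T:
            claimed.add(best_g)
            tp += 1
        else:
            fp += 1
        recall = tp / n_gt if n_gt else 0.0
        precision = tp / (tp + fp)
        points.append((recall, precision))
    return PRCurve(points=points, n_gt=n_gt)


def ap_11point(curve: PRCurve) -> float:
    """Mean interpolated precision over the 11 equally spaced recall levels."""
    if not curve.points:
        return 0.0
    return float(np.mean([curve.interp_precision(r) for r in RECALL_LEVELS]))


def ap_integral(curve: PRCurve) -> float:
    """All-point (trapezoid-free, step) AP for diagnostics."""
    if not curve.points:
        return 0.0
    recalls = sorted({r for r, _ in curve.points} | {0.0})
    area = 0.0
    prev = 0.0
    for r in recalls:
        if r > prev:
            area += (r - prev) * curve.interp_precision(r)
            prev = r
    return area


def ap75_report(
    table: OverlapTable,
    gt_index: InstanceIndex,
    pred_index: InstanceIndex,
    gt_grouping=None,
    pred_grouping=None,
    T: float = 0.75,
) -> dict:
    """AP at threshold ``T`` overall and per size group.

    Per-group AP restricts both the GT and the predictions to that group
    (prediction groups from the predictions' own masks) before ranking and
    matching; empty groups report AP 0 with an ``empty`` flag.
    """
    def _ap(gt_ids: set[int], pred_ids: set[int]) -> dict:
        if not gt_ids and not pred_ids:
            return {"ap": 0.0, "n_gt": 0, "n_pred": 0, "empty": True}
        sub = OverlapTable(
            pairs={k: v for k, v in table.pairs.items() if k[0] in gt_ids and k[1] in pred_ids},
            gt_sizes={g: s for g, s in table.gt_sizes.items() if g in gt_ids},
            pred_sizes={p: s for p, s in table.pred_sizes.items() if p in pred_ids},
        )
        ranked = RankedPredictions(
            order=sorted(pred_ids, key=lambda i: (-pred_index.sizes[i], i)),
            confidence={i: pred_index.sizes[i] for i in pred_ids},
        )
        ap = ap_11point(pr_curve(ranked, sub, T))
        return {"ap": ap, "n_gt": len(gt_ids), "n_pred": len(pred_ids), "empty": False}

    report = {"overall": _ap(set(gt_index.ids), set(pred_index.ids))}
    if gt_grouping is not None:
        if pred_grouping is None:
            raise ValueError("per-group AP requires a prediction grouping as well")
        for grp in ("small", "medium", "large"):
            gt_ids = {g for g in gt_index.ids if gt_grouping.group[g] == grp}
            pred_ids = {p for p in pred_index.ids if pred_grouping.group[p] == grp}
            report[grp] = _ap(gt_ids, pred_ids)
    return report
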
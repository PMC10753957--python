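"""Hungarian one-to-one matching and the precision/recall/accuracy scores.

Predicted and GT instances are matched by minimizing the total assignment
cost

    C(i, j) = -[IoU(g_j, p_i) >= T] - IoU(g_j, p_i) / (2N)

where T is the IoU threshold (0.75 for the standard accuracy score) and
N = min(#pred, #gt).  The indicator term drives the assignment toward the
maximum number of above-threshold matches; the IoU/(2N) term — strictly
smaller than 1/2 in total — only breaks ties among assignments with the same
number of above-threshold pairs, preferring higher-overlap partners.

Assigned pairs with IoU >= T are true positives; every other prediction is a
false positive and every other GT a false negative, giving

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    accuracy  = TP / (TP + FP + FN)

Accuracy folds both error kinds into a single ranking number and is bounded
above by both precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .overlap import OverlapTable

DEFAULT_IOU_THRESHOLD = 0.75


@dataclass
class CostMatrix:
    rows: list[int]  # pred ids
    cols: list[int]  # gt ids
    C: np.ndarray  # shape (len(rows), len(cols))
    iou: np.ndarray  # matching IoU values
    T: float
    N: int


@dataclass
class MatchResult:
    assignment: list[tuple[int, int]]  # (gt_id, pred_id) pairs, one-to-one
    pair_iou: dict[tuple[int, int], float]
    tp_pairs: list[tuple[int, int]]
    fp_pred_ids: list[int]
    fn_gt_ids: list[int]
    T: float


@dataclass
class MatchScores:
    precision: float
    recall: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    scope: str = "overall"


def build_cost_matrix(table: OverlapTable, T: float = DEFAULT_IOU_THRESHOLD) -> CostMatrix:
    """Assemble the assignment cost matrix over all pred x gt instance pairs."""
    if not (0.0 < T <= 1.0):
        raise ValueError(f"IoU threshold must be in (0, 1], got {T}")
    rows = table.pred_ids()
    cols = table.gt_ids()
    if not rows or not cols:
        raise ValueError("cost matrix requires at least one instance on each side")
    N = min(len(rows), len(cols))
    iou = np.zeros((len(rows), len(cols)))
    for (g, p), _ in table.pairs.items():
        iou[rows.index(p), cols.index(g)] = table.iou(g, p)
    C = -(iou >= T).astype(float) - iou / (2 * N)
    return CostMatrix(rows=rows, cols=cols, C=C, iou=iou, T=T, N=N)


def optimal_assignment(cost: CostMatrix) -> MatchResult:
    """Minimize the total assignment cost (rectangular Hungarian algorithm).

    Unassigned instances are implicitly matched to zero-cost dummies, which
    is exactly what a rectangular ``linear_sum_assignment`` does, since every
    real entry is <= 0.  Assigned pairs below the IoU threshold still count
    as FP + FN.
    """
    ri, ci = linear_sum_assignment(cost.C)
    assignment = []
    pair_iou = {}
    tp_pairs = []
    matched_preds: set[int] = set()
    matched_gts: set[int] = set()
    for i, j in sorted(zip(ri, ci), key=lambda t: (cost.cols[t[1]], cost.rows[t[0]])):
        p, g = cost.rows[i], cost.cols[j]
        v = float(cost.iou[i, j])
        if v <= 0.0:
            continue  # dummy pairing, not a real association
        assignment.append((g, p))
        pair_iou[(g, p)] = v
        if v >= cost.T:
            tp_pairs.append((g, p))
            matched_preds.add(p)
            matched_gts.add(g)
    fp = [p for p in cost.rows if p not in matched_preds]
    fn = [g for g in cost.cols if g not in matched_gts]
    return MatchResult(
        assignment=assignment,
        pair_iou=pair_iou,
        tp_pairs=tp_pairs,
        fp_pred_ids=fp,
        fn_gt_ids=fn,
        T=cost.T,
    )


def match(table: OverlapTable, T: float = DEFAULT_IOU_THRESHOLD) -> MatchResult:
    """Convenience: cost matrix + optimal assignment, handling empty sides."""
    if not table.gt_sizes or not table.pred_sizes:
        return MatchResult(
            assignment=[],
            pair_iou={},
            tp_pairs=[],
            fp_pred_ids=table.pred_ids(),
            fn_gt_ids=table.gt_ids(),
            T=T,
        )
    return optimal_assignment(build_cost_matrix(table, T))


def _scores(tp: int, fp: int, fn: int, scope: str) -> MatchScores:
    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    return MatchScores(
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
        accuracy=ratio(tp, tp + fp + fn),
        tp=tp,
        fp=fp,
        fn=fn,
        scope=scope,
    )


def matching_scores(
    result: MatchResult,
    gt_grouping=None,
    pred_grouping=None,
    table: OverlapTable | None = None,
    fp_bin: str = "gt",
) -> dict[str, MatchScores]:
    """Precision / recall / accuracy, overall and per size group.

    TP and FN are binned by the GT instance's group.  FP binning is governed
    by ``fp_bin``:

    - ``"gt"`` (default): a false-positive prediction inherits the group of
      its best-overlapping GT instance (requires ``table``); background FPs
      with no overlap fall back to the prediction's own group.
    - ``"pred"``: every FP uses the group computed from its own mask.

    Per-group scoring requires ``gt_grouping`` (and ``pred_grouping`` for the
    FP side); 0/0 ratios are reported as 0.
    """
    tp, fp, fn = len(result.tp_pairs), len(result.fp_pred_ids), len(result.fn_gt_ids)
    report = {"overall": _scores(tp, fp, fn, "overall")}
    if gt_grouping is None:
        return report
    if fp_bin not in ("gt", "pred"):
        raise ValueError(f"fp_bin must be 'gt' or 'pred', got {fp_bin!r}")
    if fp_bin == "gt" and table is None and result.fp_pred_ids:
        raise ValueError("fp_bin='gt' requires the overlap table")

    def fp_group(p: int) -> str:
        if fp_bin == "gt" and table is not None:
            best_g, best_iou = None, 0.0
            for (g, pp), _ in table.pairs.items():
                if pp == p:
                    v = table.iou(g, p)
                    if v > best_iou:
                        best_g, best_iou = g, v
            if best_g is not None:
                return gt_grouping.group[best_g]
        if pred_grouping is None:
            raise KeyError(f"prediction {p} has no size group")
        return pred_grouping.group[p]

    for grp in ("small", "medium", "large"):
        g_tp = sum(1 for (g, _) in result.tp_pairs if gt_grouping.group[g] == grp)
        g_fn = sum(1 for g in result.fn_gt_ids if gt_grouping.group[g] == grp)
        g_fp = sum(1 for p in result.fp_pred_ids if fp_group(p) == grp)
        report[grp] = _scores(g_tp, g_fp, g_fn, grp)
    return report
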
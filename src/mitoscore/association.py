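"""Association error taxonomy between GT and predicted instances.

Any pair (p, g) with positive overlap is *associated*.  Each GT instance then
falls into exactly one of five categories determined by the reciprocal
structure of the association graph:

- ``one_to_one``: g overlaps exactly one prediction p, and p overlaps only g;
- ``over_segmentation``: g is covered by two or more predictions, each of
  which overlaps only g (a split);
- ``under_segmentation``: g shares its single prediction p with other GT
  instances, and every GT of p overlaps only p (a merger — every merged GT
  receives the label);
- ``missing``: g overlaps no prediction;
- ``many_to_many``: any other (entangled) configuration.

Predictions that overlap no GT are *background* (false positives).  The five
GT categories are reported as percentages of the GT instance count, so they
sum to 100%; background is reported as a percentage of the prediction count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .overlap import OverlapTable

GT_CATEGORIES = (
    "one_to_one",
    "over_segmentation",
    "under_segmentation",
    "many_to_many",
    "missing",
)


@dataclass
class AssociationGraph:
    """Bipartite positive-overlap graph between predictions and GT."""

    A: set[tuple[int, int]] = field(default_factory=set)  # (pred, gt) pairs
    A_of_g: dict[int, set[int]] = field(default_factory=dict)  # gt -> pred set
    A_of_p: dict[int, set[int]] = field(default_factory=dict)  # pred -> gt set


@dataclass
class AssociationResult:
    gt_category: dict[int, str] = field(default_factory=dict)
    background_preds: set[int] = field(default_factory=set)
    n_gt: int = 0
    n_pred: int = 0


def build_association_graph(table: OverlapTable, min_overlap: int = 1) -> AssociationGraph:
    """All (pred, gt) pairs with intersection >= ``min_overlap`` voxels.

    The default of 1 voxel is the strict any-positive-overlap definition;
    raising it discounts incidental single-voxel touches from noisy decoders.
    """
    graph = AssociationGraph(
        A_of_g={int(g): set() for g in table.gt_sizes},
        A_of_p={int(p): set() for p in table.pred_sizes},
    )
    for (g, p), n in table.pairs.items():
        if n >= min_overlap:
            graph.A.add((p, g))
            graph.A_of_g[g].add(p)
            graph.A_of_p[p].add(g)
    return graph


def categorize(graph: AssociationGraph) -> AssociationResult:
    """Assign each GT instance its association category; flag background FPs."""
    result = AssociationResult(n_gt=len(graph.A_of_g), n_pred=len(graph.A_of_p))
    for g, preds in graph.A_of_g.items():
        if not preds:
            cat = "missing"
        elif len(preds) == 1:
            (p,) = preds
            partners = graph.A_of_p[p]
            if partners == {g}:
                cat = "one_to_one"
            elif all(graph.A_of_g[g2] == {p} for g2 in partners):
                cat = "under_segmentation"
            else:
                cat = "many_to_many"
        else:
            if all(graph.A_of_p[p] == {g} for p in preds):
                cat = "over_segmentation"
            else:
                cat = "many_to_many"
        result.gt_category[g] = cat
    result.background_preds = {p for p, gs in graph.A_of_p.items() if not gs}
    return result


def association_percentages(
    result: AssociationResult,
    grouping=None,
) -> dict:
    """Category percentages, overall and (optionally) per size group.

    GT categories use the GT instance count as denominator (summing to 100%);
    background uses the predicted instance count and is reported overall only,
    since a merged or background prediction has no unambiguous GT group.
    """
    def _pct(ids: list[int]) -> dict[str, float]:
        n = len(ids)
        out = {}
        for cat in GT_CATEGORIES:
            k = sum(1 for g in ids if result.gt_category[g] == cat)
            out[cat] = 100.0 * k / n if n else 0.0
        out["n_gt"] = n
        return out

    all_gt = sorted(result.gt_category)
    report = {"overall": _pct(all_gt)}
    report["overall"]["background"] = (
        100.0 * len(result.background_preds) / result.n_pred if result.n_pred else 0.0
    )
    report["overall"]["n_pred"] = result.n_pred

    if grouping is not None:
        missing = [g for g in all_gt if g not in grouping.group]
        if missing:
            raise KeyError(f"GT ids without a size group: {missing}")
        for grp in ("small", "medium", "large"):
            ids = [g for g in all_gt if grouping.group[g] == grp]
            report[grp] = _pct(ids)
    return report
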
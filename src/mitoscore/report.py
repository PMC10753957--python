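"""One-shot evaluation pipeline: volumes in, full metric panel out.

``evaluate`` runs overlap -> grouping -> Hungarian matching -> AP-75 ->
association -> split/merge on a GT/prediction pair, all off a single shared
overlap table, and returns a plain-dict report that serializes losslessly to
JSON (CSV and markdown are formatted views).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .ap import ap75_report
from .association import association_percentages, build_association_graph, categorize
from .matching import match, matching_scores
from .morphology import (
    DEFAULT_LENGTH_THRESHOLDS_UM,
    cable_lengths,
    group_by_length,
    group_by_volume,
    split_merge_histogram,
    split_merge_sets,
)
from .overlap import build_overlap_table
from .volumes import LabelVolume, build_index

SCOPES = ("overall", "small", "medium", "large")


@dataclass(frozen=True)
class EvalConfig:
    """Everything that determines an evaluation run."""

    iou_threshold: float = 0.75
    grouping: str = "length"  # "length" (cable length, um) or "volume" (voxels)
    length_thresholds_um: tuple[float, float] = DEFAULT_LENGTH_THRESHOLDS_UM
    volume_thresholds: tuple[float, float] | None = None
    min_overlap_voxels: int = 1
    fp_bin: str = "gt"
    histogram_bins: int = 15


def evaluate(gt: LabelVolume, pred: LabelVolume, config: EvalConfig = EvalConfig()) -> dict:
    """Compute the full metric panel for one GT/prediction pair."""
    if gt.shape != pred.shape:
        raise ValueError(f"[overlap] shape mismatch: gt {gt.shape} vs pred {pred.shape}")

    table = build_overlap_table(gt, pred)
    gt_index = build_index(gt)
    pred_index = build_index(pred)

    if config.grouping == "length":
        gt_lengths = cable_lengths(gt)
        gt_grouping = group_by_length(gt_lengths, config.length_thresholds_um)
        pred_grouping = group_by_length(cable_lengths(pred), config.length_thresholds_um)
    elif config.grouping == "volume":
        if config.volume_thresholds is None:
            raise ValueError("[grouping] volume grouping requires explicit voxel thresholds")
        gt_lengths = {i: float(s) for i, s in gt_index.sizes.items()}
        gt_grouping = group_by_volume(gt_index.sizes, config.volume_thresholds)
        pred_grouping = group_by_volume(pred_index.sizes, config.volume_thresholds)
    else:
        raise ValueError(f"[grouping] unknown grouping mode {config.grouping!r}")

    result = match(table, config.iou_threshold)
    scores = matching_scores(
        result,
        gt_grouping=gt_grouping if len(gt_index) else None,
        pred_grouping=pred_grouping,
        table=table,
        fp_bin=config.fp_bin,
    )
    ap = ap75_report(
        table, gt_index, pred_index,
        gt_grouping=gt_grouping if len(gt_index) else None,
        pred_grouping=pred_grouping,
        T=config.iou_threshold,
    )
    graph = build_association_graph(table, config.min_overlap_voxels)
    categories = categorize(graph)
    assoc = association_percentages(categories, gt_grouping if len(gt_index) else None)
    record = split_merge_sets(graph, categories)
    histogram = (
        split_merge_histogram(record, gt_lengths, config.histogram_bins)
        if gt_lengths
        else {"nbins": config.histogram_bins, "bins": []}
    )

    report = {
        "provenance": {
            "software": f"mitoscore {__version__}",
            "spacing_nm": list(gt.spacing_nm),
            # JSON-safe copy (tuples -> lists) so reports round-trip losslessly
            "config": json.loads(json.dumps(asdict(config))),
            "n_gt": len(gt_index),
            "n_pred": len(pred_index),
        },
        "matching": {
            scope: {
                "precision": s.precision,
                "recall": s.recall,
                "accuracy": s.accuracy,
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
            }
            for scope, s in scores.items()
        },
        "ap75": ap,
        "association": assoc,
        "split_merge": {
            "n_split_pairs": len(record.S),
            "n_merge_pairs": len(record.M),
            "splits_per_gt": {str(g): n for g, n in sorted(record.splits_per_gt.items())},
            "merges_per_pred": {str(p): n for p, n in sorted(record.merges_per_pred.items())},
            "histogram": histogram,
        },
        "grouping": {
            "mode": config.grouping,
            "gt": {str(i): g for i, g in sorted(gt_grouping.group.items())},
            "gt_lengths": {str(i): v for i, v in sorted(gt_lengths.items())},
        },
    }
    return report


def write_report(report: dict, path: str | Path, format: str = "json") -> None:
    """Serialize a report. JSON is lossless; CSV/markdown are views."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
    elif format in ("csv", "markdown"):
        df = report_frame(report)
        if format == "csv":
            df.to_csv(path, index=False)
        else:
            path.write_text(df.to_markdown(index=False))
    else:
        raise ValueError(f"unknown report format {format!r}")


def report_frame(report: dict) -> pd.DataFrame:
    """One row per scope with the headline numbers (percentages to 1 decimal)."""
    rows = []
    for scope in SCOPES:
        m = report["matching"].get(scope)
        a = report["association"].get(scope, {})
        ap = report["ap75"].get(scope, {})
        if m is None:
            continue
        rows.append(
            {
                "scope": scope,
                "ap75": round(ap.get("ap", 0.0), 2),
                "precision": round(m["precision"], 2),
                "recall": round(m["recall"], 2),
                "accuracy": round(m["accuracy"], 2),
                "tp": m["tp"],
                "fp": m["fp"],
                "fn": m["fn"],
                "one_to_one_pct": round(a.get("one_to_one", 0.0), 1),
                "over_pct": round(a.get("over_segmentation", 0.0), 1),
                "under_pct": round(a.get("under_segmentation", 0.0), 1),
                "many_pct": round(a.get("many_to_many", 0.0), 1),
                "missing_pct": round(a.get("missing", 0.0), 1),
                "background_pct": round(a["background"], 1) if "background" in a else None,
            }
        )
    return pd.DataFrame(rows)


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
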
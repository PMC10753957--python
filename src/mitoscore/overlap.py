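"""Sparse GT x prediction contingency table and pairwise IoU.

The overlap table is the single source of truth for every downstream metric
(AP, matching, association): it records, for each co-occurring pair of a
ground-truth instance A and a predicted instance B, the intersection voxel
count |A n B|, together with per-instance sizes |A| and |B|.  IoU is then

    IoU(A, B) = |A n B| / (|A| + |B| - |A n B|)

computed lazily from counts, never from re-rasterized masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import LabelVolume


@dataclass
class OverlapTable:
    """Sparse (gt_id, pred_id) -> intersection-count table plus sizes."""

    pairs: dict[tuple[int, int], int] = field(default_factory=dict)
    gt_sizes: dict[int, int] = field(default_factory=dict)
    pred_sizes: dict[int, int] = field(default_factory=dict)

    def iou(self, g: int, p: int) -> float:
        """IoU between GT instance ``g`` and predicted instance ``p``.

        Returns 0.0 for a non-overlapping (absent) pair; raises for an
        unknown id.
        """
        if g not in self.gt_sizes:
            raise KeyError(f"unknown gt id {g}")
        if p not in self.pred_sizes:
            raise KeyError(f"unknown pred id {p}")
        inter = self.pairs.get((g, p), 0)
        if inter == 0:
            return 0.0
        union = self.gt_sizes[g] + self.pred_sizes[p] - inter
        return inter / union

    def gt_ids(self) -> list[int]:
        return sorted(self.gt_sizes)

    def pred_ids(self) -> list[int]:
        return sorted(self.pred_sizes)

    def pairs_of_gt(self, g: int) -> list[int]:
        """Predicted ids overlapping GT ``g``."""
        return sorted(p for (gg, p) in self.pairs if gg == g)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per overlapping pair: gt_id, pred_id, intersection, sizes, iou."""
        rows = [
            {
                "gt_id": g,
                "pred_id": p,
                "intersection": n,
                "gt_size": self.gt_sizes[g],
                "pred_size": self.pred_sizes[p],
                "iou": self.iou(g, p),
            }
            for (g, p), n in sorted(self.pairs.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["gt_id", "pred_id", "intersection", "gt_size", "pred_size", "iou"],
        )


def build_overlap_table(gt: LabelVolume, pred: LabelVolume) -> OverlapTable:
    """Build the sparse contingency table in one linear pass over paired voxels.

    Joint labels are counted with a single ``np.unique`` over the stacked
    (gt, pred) label pairs; background (0) never enters the table, but voxels
    where only one side is background still contribute to that side's size.
    """
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    g = gt.grid.ravel()
    p = pred.grid.ravel()

    table = OverlapTable()
    gc = np.bincount(g)
    pc = np.bincount(p)
    table.gt_sizes = {int(i): int(gc[i]) for i in np.nonzero(gc)[0] if i != 0}
    table.pred_sizes = {int(i): int(pc[i]) for i in np.nonzero(pc)[0] if i != 0}

    both = (g != 0) & (p != 0)
    if both.any():
        joint = np.stack([g[both], p[both]], axis=1)
        uniq, counts = np.unique(joint, axis=0, return_counts=True)
        table.pairs = {
            (int(gg), int(pp)): int(n) for (gg, pp), n in zip(uniq, counts)
        }
    return table
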
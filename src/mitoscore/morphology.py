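"""Cable length, size grouping, and split/merger decomposition.

Mitochondria are grouped as small / medium / large by *cable length*: the
total physical length of the instance's 3D skeleton (medial axis), with the
thresholds small <= 1 um < medium < 4 um <= large.  Cable length captures
elongated, bead-on-a-string morphologies (MOAS) that voxel volume misclassifies,
which is why the legacy volume-based grouping is kept only as an explicit
config-driven mode.

Skeletonization runs on the voxel grid; anisotropy enters afterwards, as
physical edge weights on the 26-adjacency graph of skeleton voxels.  Length is
accounted on a minimum spanning tree per connected component so that thick
junction clusters left by thinning are not double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage.morphology import skeletonize

from .association import AssociationGraph, AssociationResult
from .volumes import LabelVolume

#: small/large cable-length cut points in um
DEFAULT_LENGTH_THRESHOLDS_UM = (1.0, 4.0)

GROUPS = ("small", "medium", "large")


@dataclass
class SkeletonGraph:
    """Skeleton voxels of one instance with physically weighted adjacency.

    ``nodes`` are (z, y, x) voxel coordinates; ``edges`` join 26-neighboring
    skeleton voxels with their Euclidean physical length in nm; ``tree_edges``
    is the cycle-free (minimum spanning tree) subset used for length
    accounting.
    """

    nodes: np.ndarray
    edges: list[tuple[int, int, float]]
    tree_edges: list[tuple[int, int, float]]
    n_components: int


@dataclass
class SizeGrouping:
    """Per-instance size measure and small/medium/large assignment."""

    lengths: dict[int, float]
    group: dict[int, str]
    thresholds: tuple[float, float]
    mode: str = "length"  # "length" (um) or "volume" (voxels)

    def ids_in(self, group: str) -> list[int]:
        return sorted(i for i, grp in self.group.items() if grp == group)


@dataclass
class SplitMergeRecord:
    """Association pairs routed to splits (S) vs mergers (M), with fan counts."""

    S: set[tuple[int, int]] = field(default_factory=set)  # (pred, gt) split pairs
    M: set[tuple[int, int]] = field(default_factory=set)  # (pred, gt) merger pairs
    splits_per_gt: dict[int, int] = field(default_factory=dict)
    merges_per_pred: dict[int, int] = field(default_factory=dict)


def skeletonize_instance(
    mask: np.ndarray, spacing_nm: tuple[float, float, float]
) -> SkeletonGraph:
    """Thin a binary instance mask to its 3D skeleton graph.

    Edges join 26-neighboring skeleton voxels and carry physical lengths
    derived from the (z, y, x) spacing; a minimum spanning tree per connected
    component is retained for cable-length accounting.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = skeletonize(mask)
    if not skel.any():
        # thinning can erase a tiny blob entirely; keep one representative voxel
        skel = np.zeros_like(mask)
        skel[tuple(np.argwhere(mask)[0])] = True
    nodes = np.argwhere(skel)
    coord_to_idx = {tuple(c): i for i, c in enumerate(map(tuple, nodes))}
    spacing = np.asarray(spacing_nm, dtype=float)

    edges: list[tuple[int, int, float]] = []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)  # half of the 26-neighborhood
    ]
    for i, (z, y, x) in enumerate(map(tuple, nodes)):
        for dz, dy, dx in offsets:
            j = coord_to_idx.get((z + dz, y + dy, x + dx))
            if j is not None:
                length = float(np.linalg.norm(np.array([dz, dy, dx]) * spacing))
                edges.append((i, j, length))

    n = len(nodes)
    if edges:
        ii, jj, ww = zip(*edges)
        graph = coo_matrix((ww, (ii, jj)), shape=(n, n))
        mst = minimum_spanning_tree(graph).tocoo()
        tree_edges = [
            (int(a), int(b), float(w)) for a, b, w in zip(mst.row, mst.col, mst.data)
        ]
        n_components = n - len(tree_edges)
    else:
        tree_edges = []
        n_components = n
    return SkeletonGraph(nodes=nodes, edges=edges, tree_edges=tree_edges, n_components=n_components)


def cable_length(skel: SkeletonGraph) -> float:
    """Total spanning-tree skeleton length, in um."""
    return sum(w for _, _, w in skel.tree_edges) / 1000.0


def cable_lengths(vol: LabelVolume) -> dict[int, float]:
    """Cable length in um for every instance of a label volume."""
    lengths: dict[int, float] = {}
    slices = ndimage.find_objects(vol.grid)
    for i in vol.ids():
        i = int(i)
        sl = slices[i - 1]
        # pad by 1 so thinning sees a free border
        sub = np.pad(vol.grid[sl] == i, 1)
        lengths[i] = cable_length(skeletonize_instance(sub, vol.spacing_nm))
    return lengths


def group_by_length(
    lengths: dict[int, float],
    thresholds: tuple[float, float] = DEFAULT_LENGTH_THRESHOLDS_UM,
) -> SizeGrouping:
    """Assign small / medium / large by cable length in um.

    Boundary convention: small iff length <= lo, large iff length >= hi,
    medium strictly between.
    """
    lo, hi = thresholds
    group: dict[int, str] = {}
    for i, length in lengths.items():
        if length < 0:
            raise ValueError(f"negative cable length for id {i}")
        group[i] = "small" if length <= lo else ("large" if length >= hi else "medium")
    return SizeGrouping(lengths=dict(lengths), group=group, thresholds=(lo, hi), mode="length")


def group_by_volume(
    sizes: dict[int, int], thresholds: tuple[float, float]
) -> SizeGrouping:
    """Legacy grouping on voxel counts; thresholds must be supplied explicitly."""
    if thresholds is None or len(thresholds) != 2:
        raise ValueError("volume grouping requires explicit (lo, hi) voxel thresholds")
    lo, hi = thresholds
    group: dict[int, str] = {}
    for i, size in sizes.items():
        group[i] = "small" if size <= lo else ("large" if size >= hi else "medium")
    return SizeGrouping(
        lengths={i: float(s) for i, s in sizes.items()},
        group=group,
        thresholds=(lo, hi),
        mode="volume",
    )


def group_volume(vol: LabelVolume, thresholds=DEFAULT_LENGTH_THRESHOLDS_UM) -> SizeGrouping:
    """Convenience: cable lengths + length grouping for a whole volume."""
    return group_by_length(cable_lengths(vol), thresholds)


def split_merge_sets(
    graph: AssociationGraph,
    categories: AssociationResult,
    as_printed: bool = False,
) -> SplitMergeRecord:
    """Partition non-trivial association pairs into splits (S) and mergers (M).

    Over-segmentation pairs are splits, under-segmentation pairs are mergers.
    Many-to-many pairs are routed by comparing the GT-side fan-out |A(g)| with
    the prediction-side fan-in |A'(p)|: GT fanning out over more predictions
    is a split, the converse a merger, ties go to S.  ``as_printed`` flips the
    many-to-many inequality orientation to the literal published form.
    """
    rec = SplitMergeRecord()
    for (p, g) in graph.A:
        cat = categories.gt_category[g]
        if cat == "over_segmentation":
            rec.S.add((p, g))
        elif cat == "under_segmentation":
            rec.M.add((p, g))
        elif cat == "many_to_many":
            fan_out = len(graph.A_of_g[g])   # predictions per GT
            fan_in = len(graph.A_of_p[p])    # GTs per prediction
            if as_printed:
                (rec.S if fan_in >= fan_out else rec.M).add((p, g))
            else:
                (rec.S if fan_out >= fan_in else rec.M).add((p, g))
    for (_, g) in rec.S:
        rec.splits_per_gt[g] = len(graph.A_of_g[g])
    for (p, _) in rec.M:
        rec.merges_per_pred[p] = len(graph.A_of_p[p])
    return rec


def split_merge_histogram(
    record: SplitMergeRecord,
    lengths: dict[int, float],
    nbins: int = 15,
) -> dict:
    """Bin GT cable lengths into ``nbins`` equal-width bins and summarize
    per-bin split/merger instance counts (mean, sd, occupancy).

    Splits are counted on the GT side (pieces per split GT); mergers are
    attributed to each merged GT as the fan-in of its merging prediction, so
    both series are functions of GT cable length.
    """
    if not lengths:
        raise ValueError("no GT lengths supplied")
    vals = np.array(list(lengths.values()), dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    width = (hi - lo) / nbins if hi > lo else 1.0
    edges = lo + width * np.arange(nbins + 1)

    split_counts = {g: n for g, n in record.splits_per_gt.items()}
    merge_counts: dict[int, int] = {}
    for (p, g) in record.M:
        merge_counts[g] = max(merge_counts.get(g, 0), len_of_pred_fan(record, p))

    def bin_of(length: float) -> int:
        b = int((length - lo) / width) if hi > lo else 0
        return min(b, nbins - 1)

    bins = []
    per_bin_splits: list[list[int]] = [[] for _ in range(nbins)]
    per_bin_merges: list[list[int]] = [[] for _ in range(nbins)]
    occupancy = [0] * nbins
    for g, length in lengths.items():
        b = bin_of(length)
        occupancy[b] += 1
        if g in split_counts:
            per_bin_splits[b].append(split_counts[g])
        if g in merge_counts:
            per_bin_merges[b].append(merge_counts[g])
    for b in range(nbins):
        s, m = per_bin_splits[b], per_bin_merges[b]
        bins.append(
            {
                "bin_lo": float(edges[b]),
                "bin_hi": float(edges[b + 1]),
                "n_instances": occupancy[b],
                "n_split_gt": len(s),
                "mean_splits": float(np.mean(s)) if s else 0.0,
                "sd_splits": float(np.std(s)) if s else 0.0,
                "n_merged_gt": len(m),
                "mean_merges": float(np.mean(m)) if m else 0.0,
                "sd_merges": float(np.std(m)) if m else 0.0,
            }
        )
    return {"nbins": nbins, "bins": bins}


def len_of_pred_fan(record: SplitMergeRecord, p: int) -> int:
    return record.merges_per_pred.get(p, 0)
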
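import numpy as np
import pytest

from mitoscore import (
    LabelVolume,
    build_association_graph,
    build_overlap_table,
    cable_length,
    cable_lengths,
    categorize,
    group_by_length,
    group_by_volume,
    skeletonize_instance,
    split_merge_histogram,
    split_merge_sets,
)

SPACING = (30.0, 8.0, 8.0)


def bar_volume(length, axis=0, thickness=1):
    shape = [thickness + 4] * 3
    shape[axis] = length + 4
    grid = np.zeros(shape, dtype=np.int64)
    sl = [slice(2, 2 + thickness)] * 3
    sl[axis] = slice(2, 2 + length)
    grid[tuple(sl)] = 1
    return LabelVolume(grid, SPACING)


class TestSkeleton:
    def test_single_voxel_has_no_edges(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        skel = skeletonize_instance(mask, SPACING)
        assert len(skel.nodes) == 1
        assert skel.edges == [] and skel.tree_edges == []
        assert cable_length(skel) == 0.0

    def test_straight_line_is_preserved(self):
        mask = np.zeros((14, 3, 3), dtype=bool)
        mask[2:12, 1, 1] = True
        skel = skeletonize_instance(mask, SPACING)
        assert len(skel.nodes) == 10
        assert len(skel.tree_edges) == 9

    def test_tree_edge_count_equals_nodes_minus_components(self):
        mask = np.zeros((10, 10, 3), dtype=bool)
        mask[1:4, 1, 1] = True
        mask[6:9, 8, 1] = True  # second component
        skel = skeletonize_instance(mask, SPACING)
        assert len(skel.tree_edges) == len(skel.nodes) - skel.n_components
        assert skel.n_components == 2

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            skeletonize_instance(np.zeros((3, 3, 3), dtype=bool), SPACING)

    def test_thick_bar_skeleton_matches_thin_bar_length(self):
        # a 3x3-section bar thins to the same centerline as a 1-voxel bar
        thin = cable_lengths(bar_volume(30, thickness=1))[1]
        thick = cable_lengths(bar_volume(30, thickness=3))[1]
        assert thick == pytest.approx(thin)


class TestCableLength:
    def test_straight_run_along_z(self):
        # 34 voxels -> 33 edges x 30 nm = 0.99 um
        vol = bar_volume(34, axis=0)
        assert cable_lengths(vol)[1] == pytest.approx(0.99)

    def test_straight_run_along_y_uses_8nm_spacing(self):
        vol = bar_volume(34, axis=1)
        assert cable_lengths(vol)[1] == pytest.approx(33 * 8 / 1000)

    def test_l_shape_sums_both_arms_with_one_diagonal(self):
        # arm along z (6 voxels) then arm along y (5 voxels) sharing a corner
        grid = np.zeros((10, 10, 3), dtype=np.int64)
        grid[2:8, 2, 1] = 1
        grid[7, 2:7, 1] = 1
        vol = LabelVolume(grid, SPACING)
        # thinning replaces the corner voxel with one diagonal step; hand
        # enumeration of the tree edges: 4 z-edges of 30 nm, one zy-diagonal
        # of sqrt(30^2 + 8^2) nm, 3 y-edges of 8 nm
        expected = (4 * 30 + np.sqrt(30**2 + 8**2) + 3 * 8) / 1000
        assert cable_lengths(vol)[1] == pytest.approx(expected)

    def test_linear_in_spacing(self):
        grid = bar_volume(20).grid
        one = cable_lengths(LabelVolume(grid, SPACING))[1]
        two = cable_lengths(LabelVolume(grid, tuple(2 * s for s in SPACING)))[1]
        assert two == pytest.approx(2 * one)

    def test_invariant_under_matched_axis_permutation(self):
        vol = bar_volume(25, axis=0)
        perm = (2, 0, 1)
        permuted = LabelVolume(
            np.transpose(vol.grid, perm), tuple(vol.spacing_nm[a] for a in perm)
        )
        assert cable_lengths(permuted)[1] == pytest.approx(cable_lengths(vol)[1])


class TestGrouping:
    @pytest.mark.parametrize(
        "length,expected",
        [(0.5, "small"), (1.0, "small"), (2.0, "medium"), (3.99, "medium"), (4.0, "large"), (7.0, "large")],
    )
    def test_length_boundaries(self, length, expected):
        grouping = group_by_length({1: length})
        assert grouping.group[1] == expected

    def test_negative_length_raises(self):
        with pytest.raises(ValueError):
            group_by_length({1: -0.1})

    def test_volume_grouping_mirrors_boundary_convention(self):
        grouping = group_by_volume({1: 50, 2: 100, 3: 500, 4: 1000, 5: 5000}, (100, 1000))
        assert grouping.group == {1: "small", 2: "small", 3: "medium", 4: "large", 5: "large"}

    def test_volume_grouping_requires_thresholds(self):
        with pytest.raises((TypeError, ValueError)):
            group_by_volume({1: 50}, None)

    def test_every_instance_grouped_once(self):
        lengths = {i: float(i) for i in range(1, 9)}
        grouping = group_by_length(lengths)
        assert sorted(grouping.group) == sorted(lengths)
        counts = sum(len(grouping.ids_in(g)) for g in ("small", "medium", "large"))
        assert counts == len(lengths)


def association_of(gt_grid, pred_grid):
    gt = LabelVolume(gt_grid, SPACING)
    pred = LabelVolume(pred_grid, SPACING)
    graph = build_association_graph(build_overlap_table(gt, pred))
    return graph, categorize(graph)


class TestSplitMerge:
    def test_four_way_split_routes_to_s(self):
        gt = np.zeros((1, 1, 12), dtype=np.int64)
        gt[0, 0] = 1
        pred = np.zeros((1, 1, 12), dtype=np.int64)
        for i in range(4):
            pred[0, 0, 3 * i : 3 * (i + 1)] = i + 1
        record = split_merge_sets(*association_of(gt, pred))
        assert record.splits_per_gt == {1: 4}
        assert record.M == set()

    def test_three_way_merge_routes_to_m(self):
        gt = np.zeros((1, 1, 12), dtype=np.int64)
        gt[0, 0, :4] = 1
        gt[0, 0, 4:8] = 2
        gt[0, 0, 8:] = 3
        pred = np.zeros((1, 1, 12), dtype=np.int64)
        pred[0, 0] = 1
        record = split_merge_sets(*association_of(gt, pred))
        assert record.merges_per_pred == {1: 3}
        assert record.S == set()

    def test_many_to_many_routing_matches_hand_enumeration(self):
        # p1 overlaps {g1, g2}; g1 overlaps {p1, p2}; g2 overlaps only p1
        gt = np.zeros((1, 1, 12), dtype=np.int64)
        gt[0, 0, :6] = 1
        gt[0, 0, 6:] = 2
        pred = np.zeros((1, 1, 12), dtype=np.int64)
        pred[0, 0, 3:9] = 1
        pred[0, 0, :3] = 2
        graph, cats = association_of(gt, pred)
        assert cats.gt_category[1] == "many_to_many"
        record = split_merge_sets(graph, cats)
        # hand enumeration: A = {(1,1),(1,2),(2,1)};
        # (p1,g1): |A(g1)|=2 = |A'(p1)|=2 -> tie -> S
        # (p2,g1): |A(g1)|=2 > |A'(p2)|=1 -> S
        # (p1,g2): |A(g2)|=1 < |A'(p1)|=2 -> M
        assert record.S == {(1, 1), (2, 1)}
        assert record.M == {(1, 2)}

    def test_pair_routing_partitions_non_trivial_pairs(self):
        rng = np.random.default_rng(7)
        for seed in range(10):
            r = np.random.default_rng(seed)
            gt = r.integers(0, 4, size=(8, 8, 8)).astype(np.int64)
            pred = r.integers(0, 5, size=(8, 8, 8)).astype(np.int64)
            graph, cats = association_of(gt, pred)
            record = split_merge_sets(graph, cats)
            assert record.S.isdisjoint(record.M)
            nontrivial = {
                (p, g)
                for (p, g) in graph.A
                if cats.gt_category[g] in ("over_segmentation", "under_segmentation", "many_to_many")
            }
            assert record.S | record.M == nontrivial

    def test_as_printed_mode_flips_many_to_many_routing(self):
        gt = np.zeros((1, 1, 12), dtype=np.int64)
        gt[0, 0, :6] = 1
        gt[0, 0, 6:] = 2
        pred = np.zeros((1, 1, 12), dtype=np.int64)
        pred[0, 0, 3:9] = 1
        pred[0, 0, :3] = 2
        graph, cats = association_of(gt, pred)
        record = split_merge_sets(graph, cats, as_printed=True)
        assert (1, 2) in record.S  # |A'(p1)| >= |A(g2)| as printed


class TestHistogram:
    def test_single_gt_occupies_one_bin(self):
        gt = np.zeros((1, 1, 12), dtype=np.int64)
        gt[0, 0] = 1
        pred = np.zeros((1, 1, 12), dtype=np.int64)
        pred[0, 0, :6] = 1
        pred[0, 0, 6:] = 2
        record = split_merge_sets(*association_of(gt, pred))
        hist = split_merge_histogram(record, {1: 0.5}, nbins=15)
        occupied = [b for b in hist["bins"] if b["n_instances"]]
        assert len(occupied) == 1
        assert occupied[0]["n_split_gt"] == 1
        assert occupied[0]["mean_splits"] == 2.0

    def test_equal_lengths_share_a_bin(self):
        record = split_merge_sets(
            *association_of(np.zeros((1, 1, 2), dtype=np.int64), np.zeros((1, 1, 2), dtype=np.int64))
        )
        hist = split_merge_histogram(record, {1: 2.0, 2: 2.0}, nbins=15)
        assert sum(b["n_instances"] for b in hist["bins"]) == 2
        assert max(b["n_instances"] for b in hist["bins"]) == 2

    def test_splits_increase_with_length_in_constructed_scene(self):
        # bars of increasing length split into increasing piece counts
        nz = 120
        gt = np.zeros((nz, 20, 3), dtype=np.int64)
        pred = np.zeros((nz, 20, 3), dtype=np.int64)
        next_pred = 1
        specs = [(20, 2, 2), (50, 8, 3), (100, 14, 4)]  # (length, y, pieces)
        for gid, (length, y, k) in enumerate(specs, start=1):
            gt[2 : 2 + length, y, 1] = gid
            for piece in np.array_split(np.arange(2, 2 + length), k):
                pred[piece, y, 1] = next_pred
                next_pred += 1
        gtv = LabelVolume(gt, SPACING)
        predv = LabelVolume(pred, SPACING)
        graph = build_association_graph(build_overlap_table(gtv, predv))
        record = split_merge_sets(graph, categorize(graph))
        lengths = cable_lengths(gtv)
        hist = split_merge_histogram(record, lengths, nbins=5)
        means = [b["mean_splits"] for b in hist["bins"] if b["n_split_gt"]]
        assert means == sorted(means)
        assert record.splits_per_gt == {1: 2, 2: 3, 3: 4}
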
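"""Ground-truth filtering, skeletons, edit counts, VOI, descriptor errors."""

import itertools

import numpy as np
import pytest

from bootseg.evaluate import (
    filter_ground_truth,
    lsd_error_map,
    min_cut_metric,
    skeletonize,
    variation_of_information,
)
from bootseg.postproc import FragmentVolume, RegionAdjacencyGraph
from bootseg.synth import SynthParams, generate_labels
from bootseg.targets import compute_lsd
from bootseg.volumes import LabelVolume, Skeleton
from oracles import brute_force_voi, exhaustive_edit_count

VOXEL = (10.0, 10.0, 10.0)


class TestFilterGroundTruth:
    def test_size_threshold_is_strict_less_than(self):
        data = np.zeros((8, 32, 32), np.uint64)
        data[0, :20, :25] = 1   # 500 voxels ...
        data[0, 0, 0] = 0       # ... minus one: removed (smaller than 500)
        data[4:6, :10, :25] = 2  # exactly 500 voxels: kept
        lv = LabelVolume(data)
        out = filter_ground_truth(lv, min_size=500)
        kept_sizes = [int((out.data == i).sum()) for i in out.ids()]
        assert kept_sizes == [500]

    def test_empty_volume_stays_empty(self):
        out = filter_ground_truth(LabelVolume(np.zeros((4, 4, 4), np.uint64)))
        assert not out.data.any()

    def test_disconnected_parts_get_distinct_ids(self):
        data = np.zeros((4, 8, 100), np.uint64)
        data[:, :, :20] = 7     # 4*8*20 = 640 voxels
        data[:, :, 50:70] = 7   # disconnected second part, 640 voxels
        out = filter_ground_truth(LabelVolume(data), min_size=500)
        assert len(out.ids()) == 2

    def test_idempotent(self, synthetic_volume):
        once = filter_ground_truth(synthetic_volume, min_size=200)
        twice = filter_ground_truth(once, min_size=200)
        np.testing.assert_array_equal(once.data, twice.data)


class TestSkeletonize:
    def test_straight_tube_becomes_path_of_matching_length(self):
        data = np.zeros((5, 5, 24), np.uint64)
        data[2, 2, 2:22] = 4  # 1-voxel tube, 20 voxels long
        sks = skeletonize(LabelVolume(data, voxel_size=VOXEL), prune_length=0.0)
        assert len(sks) == 1
        sk = sks[0]
        degrees = {}
        for a, b in sk.edges:
            degrees[a] = degrees.get(a, 0) + 1
            degrees[b] = degrees.get(b, 0) + 1
        assert max(degrees.values()) <= 2  # a simple path
        tube_length = 20 * VOXEL[2]
        assert abs(sk.path_length() - tube_length) <= 2 * VOXEL[2]

    def test_single_voxel_object(self):
        data = np.zeros((5, 5, 5), np.uint64)
        data[2, 2, 2] = 1
        (sk,) = skeletonize(LabelVolume(data, voxel_size=VOXEL))
        assert len(sk.nodes) == 1
        assert sk.edges == []
        assert sk.path_length() == 0.0

    def test_nodes_lie_inside_their_object(self, synthetic_volume):
        filtered = filter_ground_truth(synthetic_volume, min_size=200)
        for sk in skeletonize(filtered):
            for pos in sk.nodes.values():
                idx = tuple(int(np.floor((p - o) / v)) for p, o, v in
                            zip(pos, filtered.offset, filtered.voxel_size))
                assert filtered.data[idx] == sk.object_id

    def test_skeletons_are_connected(self, synthetic_volume):
        import networkx as nx

        filtered = filter_ground_truth(synthetic_volume, min_size=200)
        for sk in skeletonize(filtered):
            g = nx.Graph()
            g.add_nodes_from(sk.nodes)
            g.add_edges_from(sk.edges)
            assert nx.is_connected(g)


def _abstract_instance(fragments, frag_segment, skeleton_fragments, rag_edges):
    """Build volumes/graph objects for a 1D chain of unit fragments.

    ``fragments``: number of fragments (ids 1..F laid out along x).
    ``frag_segment``: fragment id -> segment id.
    ``skeleton_fragments``: dict skeleton id -> list of fragment ids; each
    skeleton gets one node per listed fragment, chained in order.
    """
    F = fragments
    frag = np.arange(1, F + 1, dtype=np.uint64).reshape(1, 1, F)
    seg = np.array([[ [frag_segment[f] for f in range(1, F + 1)] ]], dtype=np.uint64)
    frag_vol = FragmentVolume(LabelVolume(frag), 0.5)
    seg_vol = LabelVolume(seg)
    rag = RegionAdjacencyGraph()
    for f in range(1, F + 1):
        rag.graph.add_node(f, centroid=(0.5, 0.5, f - 0.5))
    for u, v in rag_edges:
        rag.graph.add_edge(u, v, score=0.9, aff_sum=0.9, pair_count=1)
    skeletons = []
    node_segment, node_fragment = {}, {}
    skeleton_nodes, skeleton_edges = {}, {}
    next_node = 0
    for sk_id in sorted(skeleton_fragments):
        frags = skeleton_fragments[sk_id]
        nodes = {}
        local = []
        for f in frags:
            nid = next_node
            next_node += 1
            nodes[nid] = (0.5, 0.5, f - 0.5)  # voxel-center of fragment f
            local.append(nid)
            node_segment[nid] = frag_segment[f]
            node_fragment[nid] = f
        edges = list(zip(local[:-1], local[1:]))
        skeletons.append(Skeleton(object_id=sk_id, nodes=nodes, edges=edges))
        skeleton_nodes[sk_id] = local
        skeleton_edges[sk_id] = edges
    oracle_inputs = (skeleton_nodes, skeleton_edges, node_segment, node_fragment,
                     {frozenset(e) for e in rag_edges}, frag_segment)
    return skeletons, seg_vol, rag, frag_vol, oracle_inputs


class TestMinCutMetric:
    def test_perfect_segmentation_has_zero_edits(self, synthetic_volume):
        from bootseg.postproc import build_rag, watershed_fragments
        from bootseg.targets import compute_affinities

        filtered = filter_ground_truth(synthetic_volume, min_size=200)
        affs = compute_affinities(filtered)
        frags = watershed_fragments(affs, 0.5)
        rag = build_rag(frags, affs)
        skeletons = skeletonize(filtered)
        edits = min_cut_metric(skeletons, filtered, rag, frags)
        assert edits.splits == 0 and edits.merges == 0
        assert edits.per_object == 0.0

    def test_alternating_segments_count_two_splits(self):
        skeletons, seg, rag, frags, _ = _abstract_instance(
            fragments=3, frag_segment={1: 1, 2: 2, 3: 1},
            skeleton_fragments={1: [1, 2, 3]}, rag_edges=[])
        edits = min_cut_metric(skeletons, seg, rag, frags)
        assert edits.splits == 2
        assert edits.merges == 0

    def test_path_merge_needs_one_cut(self):
        skeletons, seg, rag, frags, _ = _abstract_instance(
            fragments=3, frag_segment={1: 1, 2: 1, 3: 1},
            skeleton_fragments={1: [1], 2: [3]},
            rag_edges=[(1, 2), (2, 3)])
        edits = min_cut_metric(skeletons, seg, rag, frags)
        assert edits.merges == 1
        assert edits.splits == 0

    def test_matches_exhaustive_search_on_random_instances(self, rng):
        for trial in range(40):
            F = int(rng.integers(2, 7))
            n_seg = int(rng.integers(1, 4))
            frag_segment = {f: int(rng.integers(1, n_seg + 1))
                            for f in range(1, F + 1)}
            K = int(rng.integers(2, 4))
            skeleton_fragments = {}
            for sk in range(1, K + 1):
                n_nodes = int(rng.integers(1, 4))
                skeleton_fragments[sk] = [int(rng.integers(1, F + 1))
                                          for _ in range(n_nodes)]
            pairs = list(itertools.combinations(range(1, F + 1), 2))
            rng.shuffle(pairs)
            rag_edges = pairs[:int(rng.integers(0, min(len(pairs), 8) + 1))]
            skeletons, seg, rag, frags, oracle_inputs = _abstract_instance(
                F, frag_segment, skeleton_fragments, rag_edges)
            got = min_cut_metric(skeletons, seg, rag, frags)
            want_splits, want_merges = exhaustive_edit_count(*oracle_inputs)
            assert (got.splits, got.merges) == (want_splits, want_merges), (
                trial, frag_segment, skeleton_fragments, rag_edges)

    def test_split_perturbation_monotonicity(self, synthetic_volume):
        """Splitting a perfect segmentation adds splits, never merges."""
        filtered = filter_ground_truth(synthetic_volume, min_size=200)
        skeletons = skeletonize(filtered)
        perfect = min_cut_metric(
            skeletons, filtered, RegionAdjacencyGraph(),
            FragmentVolume(filtered, 0.5))
        split = filtered.data.copy()
        bump = int(split.max()) + 1
        half = split.shape[2] // 2
        right = split[:, :, half:]
        right[right > 0] += bump
        split_vol = LabelVolume(split, filtered.voxel_size)
        perturbed = min_cut_metric(
            skeletons, split_vol, RegionAdjacencyGraph(),
            FragmentVolume(split_vol, 0.5))
        assert perturbed.splits > perfect.splits
        assert perturbed.merges == 0


class TestVariationOfInformation:
    def test_identical_labelings_give_zero(self, synthetic_volume):
        voi = variation_of_information(synthetic_volume, synthetic_volume)
        assert voi.voi_split == pytest.approx(0.0, abs=1e-12)
        assert voi.voi_merge == pytest.approx(0.0, abs=1e-12)

    def test_equal_halves_split_is_one_bit(self):
        gt = LabelVolume(np.full((2, 4, 8), 1, np.uint64))
        seg = np.ones((2, 4, 8), np.uint64)
        seg[:, :, 4:] = 2
        voi = variation_of_information(LabelVolume(seg), gt)
        assert voi.voi_split == pytest.approx(1.0)
        assert voi.voi_merge == pytest.approx(0.0)

    def test_matches_brute_force_on_random_volume(self, rng):
        seg = LabelVolume(rng.integers(0, 3, (6, 6, 6)).astype(np.uint64))
        gt = LabelVolume(rng.integers(0, 4, (6, 6, 6)).astype(np.uint64))
        voi = variation_of_information(seg, gt)
        want_split, want_merge = brute_force_voi(seg.data, gt.data)
        assert voi.voi_split == pytest.approx(want_split)
        assert voi.voi_merge == pytest.approx(want_merge)

    def test_symmetry_on_foreground_matched_volumes(self, rng):
        a = LabelVolume(rng.integers(1, 4, (5, 5, 5)).astype(np.uint64))
        b = LabelVolume(rng.integers(1, 5, (5, 5, 5)).astype(np.uint64))
        ab = variation_of_information(a, b)
        ba = variation_of_information(b, a)
        assert ab.voi_split == pytest.approx(ba.voi_merge)
        assert ab.voi_merge == pytest.approx(ba.voi_split)

    def test_no_foreground_is_an_error(self):
        empty = LabelVolume(np.zeros((3, 3, 3), np.uint64))
        with pytest.raises(ValueError):
            variation_of_information(empty, empty)


class TestLsdErrorMap:
    SIGMA = (120.0, 80.0, 80.0)

    def test_self_comparison_is_identically_zero(self, synthetic_volume):
        lsds = compute_lsd(synthetic_volume, self.SIGMA, 3)
        emap, emask = lsd_error_map(lsds, synthetic_volume, self.SIGMA)
        assert not emap.data.any()
        assert not emask.any()

    def test_isolated_voxel_error_removed_by_opening(self, synthetic_volume):
        lsds = compute_lsd(synthetic_volume, self.SIGMA, 3)
        noisy = lsds.data.copy()
        noisy[:, 24, 24, 24] = np.clip(noisy[:, 24, 24, 24] + 0.9, 0, 1)
        from bootseg.volumes import VolumeGrid

        noisy_grid = VolumeGrid(noisy, lsds.voxel_size, lsds.offset,
                                semantic="descriptor")
        emap, emask = lsd_error_map(noisy_grid, synthetic_volume, self.SIGMA,
                                    error_threshold=0.25, opening_radius=1.0)
        assert emap.data[24, 24, 24] > 0.25
        assert not emask[24, 24, 24]

    def test_merge_error_blob_survives_opening(self, synthetic_volume):
        lsds = compute_lsd(synthetic_volume, self.SIGMA, 3)
        merged = synthetic_volume.data.copy()
        ids = synthetic_volume.ids()
        # merge the two largest touching objects into one id
        sizes = [(int((merged == i).sum()), int(i)) for i in ids]
        sizes.sort(reverse=True)
        a, b = sizes[0][1], sizes[1][1]
        merged[merged == b] = a
        merged_vol = LabelVolume(merged, synthetic_volume.voxel_size)
        emap, emask = lsd_error_map(lsds, merged_vol, self.SIGMA,
                                    error_threshold=0.25, opening_radius=1.0)
        assert emask.any()

    def test_shape_mismatch_rejected(self, synthetic_volume):
        bad = compute_lsd(LabelVolume(synthetic_volume.data[:24].copy(),
                                      synthetic_volume.voxel_size),
                          self.SIGMA, 3)
        with pytest.raises(ValueError):
            lsd_error_map(bad, synthetic_volume, self.SIGMA)
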
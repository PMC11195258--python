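"""Watershed fragments, region adjacency graph, hierarchical agglomeration."""

import numpy as np
import pytest

from bootseg.postproc import (
    FragmentVolume,
    RegionAdjacencyGraph,
    agglomerate,
    build_rag,
    grid_search,
    segment,
    watershed_fragments,
)
from bootseg.synth import SynthParams, generate_labels
from bootseg.targets import AffinityGrid, compute_affinities
from bootseg.evaluate import variation_of_information
from bootseg.volumes import LabelVolume
from oracles import brute_force_agglomerate


def _affs_of(labels: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> AffinityGrid:
    return compute_affinities(LabelVolume(labels.astype(np.uint64),
                                          voxel_size=voxel_size))


class TestWatershedFragments:
    def test_all_ones_give_single_fragment(self):
        affs = _affs_of(np.ones((8, 8, 8)))
        frags = watershed_fragments(affs, 0.5)
        assert len(np.unique(frags.data)) == 1
        assert np.all(frags.data == frags.data[0, 0, 0])
        assert frags.data[0, 0, 0] > 0

    def test_all_zero_affinities_give_empty_fragments(self):
        data = np.zeros((3, 8, 8, 8), np.float32)
        affs = AffinityGrid(data)
        frags = watershed_fragments(affs, 0.5)
        assert not frags.data.any()

    def test_two_blocks_split_by_zero_faces(self):
        labels = np.ones((8, 16, 8), np.uint64)
        labels[:, 8:, :] = 2
        affs = _affs_of(labels)
        frags = watershed_fragments(affs, 0.5)
        ids_a = np.unique(frags.data[:, :8, :])
        ids_b = np.unique(frags.data[:, 8:, :])
        assert len(ids_a) == 1 and len(ids_b) == 1
        assert ids_a[0] != ids_b[0]
        assert ids_a[0] > 0 and ids_b[0] > 0

    def test_fragments_never_span_zero_affinity_faces(self, synthetic_volume):
        affs = compute_affinities(synthetic_volume)
        frags = watershed_fragments(affs, 0.5).data
        for d, off in enumerate(affs.neighborhood):
            src = tuple(slice(max(-o, 0), min(n - o, n))
                        for o, n in zip(off, frags.shape))
            dst = tuple(slice(max(o, 0), min(n + o, n))
                        for o, n in zip(off, frags.shape))
            same_frag = (frags[src] == frags[dst]) & (frags[src] > 0)
            assert np.all(affs.data[d][src][same_frag] > 0)


class TestRegionAdjacencyGraph:
    def test_single_fragment_graph(self):
        affs = _affs_of(np.ones((6, 6, 6)))
        frags = watershed_fragments(affs, 0.5)
        rag = build_rag(frags, affs)
        assert rag.graph.number_of_nodes() == 1
        assert rag.graph.number_of_edges() == 0

    def test_edge_score_is_face_mean(self):
        # two 1x1x2-fragment bars sharing 4 face pairs along y
        frag = np.zeros((1, 2, 4), np.uint64)
        frag[0, 0, :] = 1
        frag[0, 1, :] = 2
        data = np.zeros((3, 1, 2, 4), np.float32)
        data[1, 0, 1, :] = [0.2, 0.4, 0.6, 0.8]  # bonds of row 1 to row 0
        affs = AffinityGrid(data)
        rag = build_rag(FragmentVolume(LabelVolume(frag), 0.5), affs)
        assert rag.graph[1][2]["score"] == pytest.approx(0.5)
        assert rag.graph[1][2]["pair_count"] == 4

    def test_non_touching_fragments_have_no_edge(self):
        frag = np.zeros((1, 1, 5), np.uint64)
        frag[0, 0, 0] = 1
        frag[0, 0, 4] = 2
        affs = AffinityGrid(np.ones((3, 1, 1, 5), np.float32))
        rag = build_rag(FragmentVolume(LabelVolume(frag), 0.5), affs)
        assert rag.graph.number_of_edges() == 0

    def test_centroids_in_world_units(self):
        frag = np.zeros((2, 2, 2), np.uint64)
        frag[:, :, :1] = 1
        frag[:, :, 1:] = 2
        affs = AffinityGrid(np.ones((3, 2, 2, 2), np.float32),
                            voxel_size=(40.0, 8.0, 8.0))
        rag = build_rag(FragmentVolume(LabelVolume(frag, (40.0, 8.0, 8.0)), 0.5), affs)
        assert rag.graph.nodes[1]["centroid"] == pytest.approx((20.0, 4.0, 0.0))


def _rag_from_edges(edges):
    """edges: {(u, v): (aff_sum, pair_count)}"""
    rag = RegionAdjacencyGraph()
    nodes = sorted({n for e in edges for n in e})
    for n in nodes:
        rag.graph.add_node(n, centroid=(0.0, 0.0, 0.0))
    for (u, v), (s, c) in edges.items():
        rag.graph.add_edge(u, v, score=s / c, aff_sum=s, pair_count=c)
    return rag, nodes


class TestAgglomerate:
    def test_threshold_zero_merges_each_component(self):
        rag, _ = _rag_from_edges({(1, 2): (0.1, 1), (2, 3): (0.05, 1),
                                  (4, 5): (0.2, 1)})
        mapping = agglomerate(rag, 0.0)
        assert mapping[1] == mapping[2] == mapping[3]
        assert mapping[4] == mapping[5]
        assert mapping[1] != mapping[4]

    def test_threshold_above_one_is_identity(self):
        rag, nodes = _rag_from_edges({(1, 2): (0.9, 1), (2, 3): (0.99, 1)})
        mapping = agglomerate(rag, 1.0 + 1e-9)
        assert all(mapping[n] == n for n in nodes)

    def test_chain_merges_only_strong_edge(self):
        """A-B (0.9) merges at 0.5; the recomputed (A,B)-C score stays 0.3."""
        rag, _ = _rag_from_edges({(1, 2): (0.9, 1), (2, 3): (0.3, 1)})
        mapping = agglomerate(rag, 0.5)
        assert mapping[1] == mapping[2]
        assert mapping[3] != mapping[1]

    def test_matches_brute_force_on_random_rags(self, rng):
        for trial in range(60):
            n = int(rng.integers(2, 9))
            nodes = list(range(1, n + 1))
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        cnt = int(rng.integers(1, 5))
                        edges[(nodes[i], nodes[j])] = (
                            float(rng.random() * cnt), cnt)
            if not edges:
                continue
            threshold = float(rng.random())
            rag, rag_nodes = _rag_from_edges(edges)
            got = agglomerate(rag, threshold)
            want = brute_force_agglomerate(
                rag_nodes, {frozenset(e): v for e, v in edges.items()}, threshold)
            assert got == want, (trial, edges, threshold)

    def test_monotone_segment_count_in_threshold(self, synthetic_volume):
        affs = compute_affinities(synthetic_volume)
        frags = watershed_fragments(affs, 0.5)
        rag = build_rag(frags, affs)
        counts = []
        for t in (0.1, 0.3, 0.5, 0.7, 0.9):
            mapping = agglomerate(rag, t)
            counts.append(len(set(mapping.values())))
        assert counts == sorted(counts)


class TestSegment:
    def test_recovers_ground_truth_from_perfect_affinities(self):
        labels = generate_labels(SynthParams(shape=(64, 64, 64),
                                             num_objects=(20, 30), seed=55))
        affs = compute_affinities(labels)
        seg = segment(affs, 0.5, 0.5)
        voi = variation_of_information(seg, labels)
        assert voi.sum < 0.1

    def test_empty_affinities_give_empty_segmentation(self):
        affs = AffinityGrid(np.zeros((3, 6, 6, 6), np.float32))
        seg = segment(affs, 0.5, 0.5)
        assert not seg.data.any()

    def test_output_ids_consecutive_from_one(self, synthetic_volume):
        affs = compute_affinities(synthetic_volume)
        seg = segment(affs, 0.5, 0.5)
        ids = np.unique(seg.data)
        ids = ids[ids > 0]
        np.testing.assert_array_equal(ids, np.arange(1, len(ids) + 1))


class TestGridSearch:
    def test_single_cell_grid(self, synthetic_volume):
        affs = compute_affinities(synthetic_volume)
        rows, best = grid_search(affs, synthetic_volume, [0.5], [0.5])
        assert len(rows) == 1
        assert best == rows[0]

    def test_argmin_is_minimal_and_deterministic(self, synthetic_volume):
        affs = compute_affinities(synthetic_volume)
        rows1, best1 = grid_search(affs, synthetic_volume, [0.3, 0.5], [0.5, 0.9])
        rows2, best2 = grid_search(affs, synthetic_volume, [0.3, 0.5], [0.5, 0.9])
        assert rows1 == rows2 and best1 == best2
        assert all(best1["score"] <= r["score"] for r in rows1)

    def test_empty_grid_rejected(self, synthetic_volume):
        affs = compute_affinities(synthetic_volume)
        with pytest.raises(ValueError):
            grid_search(affs, synthetic_volume, [], [0.5])
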
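"""Affinities to instance segmentation.

Pipeline: threshold the channel-mean affinity into a foreground mask,
compute an anisotropy-aware Euclidean distance transform inside it, take
plateau-merged local maxima as seeds, flood a watershed into supervoxel
fragments, connect touching fragments in a region adjacency graph scored
by mean face affinity, and hierarchically merge edges in decreasing score
order down to a threshold.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .targets import AffinityGrid
from .volumes import LabelVolume, relabel_consecutive

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentVolume",
    "RegionAdjacencyGraph",
    "watershed_fragments",
    "build_rag",
    "agglomerate",
    "segment",
    "grid_search",
]

#: local-maximum footprint in voxels (z, y, x); wide in-plane because
#: serial-section data is coarse along z
DEFAULT_SEED_FOOTPRINT = (3, 9, 9)


@dataclass
class FragmentVolume:
    """Watershed supervoxels; 0 marks unsegmented background."""

    labels: LabelVolume
    boundary_threshold: float

    @property
    def data(self) -> np.ndarray:
        return self.labels.data


@dataclass
class RegionAdjacencyGraph:
    """Touching-fragment graph with affinity-derived merge scores.

    ``graph`` nodes carry fragment centroids (world nm); each edge stores
    ``score`` (mean affinity over the face voxel-pairs joining the two
    fragments) plus the underlying ``aff_sum`` / ``pair_count`` so cluster
    scores can be recomputed exactly during agglomeration.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def boundary_mask(affs: AffinityGrid, boundary_threshold: float) -> np.ndarray:
    """Foreground = voxels with at least one above-threshold touching bond.

    Each voxel touches channel d both at itself and at its partner on the
    other side; out-of-bounds entries never contribute.  A voxel all of
    whose bonds sit at or below the threshold (true background, or an
    isolated single-voxel object) is unsegmentable and stays background.
    """
    shape = affs.spatial_shape
    best = np.zeros(shape, dtype=np.float64)
    for d, off in enumerate(affs.neighborhood):
        src = tuple(slice(max(-o, 0), min(n - o, n)) for o, n in zip(off, shape))
        dst = tuple(slice(max(o, 0), min(n + o, n)) for o, n in zip(off, shape))
        vals = affs.data[d][src]
        np.maximum(best[src], vals, out=best[src])
        np.maximum(best[dst], vals, out=best[dst])
    return best > boundary_threshold


def _bond_components(affs: AffinityGrid, mask: np.ndarray,
                     boundary_threshold: float) -> np.ndarray:
    """Connected components of the above-threshold bond graph inside mask.

    Fragments may never straddle a bond at or below the boundary threshold,
    so flooding is confined to these components.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    shape = affs.spatial_shape
    n = int(np.prod(shape))
    flat = np.arange(n).reshape(shape)
    rows, cols = [], []
    for d, off in enumerate(affs.neighborhood):
        src = tuple(slice(max(-o, 0), min(s - o, s)) for o, s in zip(off, shape))
        dst = tuple(slice(max(o, 0), min(s + o, s)) for o, s in zip(off, shape))
        passable = (affs.data[d][src] > boundary_threshold) & mask[src] & mask[dst]
        rows.append(flat[src][passable].ravel())
        cols.append(flat[dst][passable].ravel())
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:  # pragma: no cover - empty neighborhood is rejected earlier
        r = c = np.empty(0, dtype=int)
    g = coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)), shape=(n, n))
    _, comp = connected_components(g, directed=False)
    comp = comp.reshape(shape) + 1
    comp[~mask] = 0
    return comp


def watershed_fragments(affs: AffinityGrid, boundary_threshold: float,
                        seed_footprint: Sequence[int] = DEFAULT_SEED_FOOTPRINT
                        ) -> FragmentVolume:
    """Seeded watershed over-segmentation of thresholded affinities.

    The channel-mean mask defines the foreground; seeds are plateau-merged
    local maxima of the anisotropy-aware distance transform; basins flood
    by watershed on the negative distance transform, gated so that no
    fragment ever spans a bond at or below the boundary threshold (in
    particular, never a 0-affinity face of ground-truth affinities).
    """
    mask = boundary_mask(affs, boundary_threshold)
    if not mask.any():
        logger.warning("no foreground at boundary threshold %.3f", boundary_threshold)
        empty = LabelVolume(np.zeros(affs.spatial_shape, np.uint64),
                            affs.voxel_size, affs.offset)
        return FragmentVolume(empty, boundary_threshold)

    dt = ndimage.distance_transform_edt(mask, sampling=affs.voxel_size)
    footprint = np.ones(tuple(seed_footprint), dtype=bool)
    local_max = (dt == ndimage.maximum_filter(dt, footprint=footprint)) & mask
    # plateau merge: connected runs of maxima become one seed
    markers, _ = ndimage.label(local_max, structure=np.ones((3, 3, 3), dtype=bool))
    basins = watershed(-dt, markers, mask=mask)

    comp = _bond_components(affs, mask, boundary_threshold)
    # a fragment is a face-connected piece of (basin ∩ bond-component)
    pair = basins.astype(np.int64) * (int(comp.max()) + 1) + comp.astype(np.int64)
    pair[~mask] = 0
    from skimage.measure import label as cc_label

    fragments = cc_label(pair, background=0, connectivity=1).astype(np.uint64)
    lv = LabelVolume(fragments, affs.voxel_size, affs.offset)
    return FragmentVolume(lv, boundary_threshold)


def build_rag(fragments: FragmentVolume, affs: AffinityGrid) -> RegionAdjacencyGraph:
    """Region adjacency graph of face-touching fragments.

    Edge score = mean predicted affinity over all face voxel-pairs spanning
    the two fragments, taken from the channel matching the face orientation.
    """
    frag = fragments.data
    if frag.shape != affs.spatial_shape:
        raise ValueError("fragment and affinity shapes must align")
    rag = RegionAdjacencyGraph()
    vs = np.asarray(affs.voxel_size)
    off0 = np.asarray(affs.offset)

    ids = np.unique(frag)
    ids = ids[ids > 0]
    if ids.size:
        # centroids in world coordinates
        centers = ndimage.center_of_mass(frag > 0, frag, index=ids)
        for fid, com in zip(ids, centers):
            rag.graph.add_node(int(fid), centroid=tuple(np.asarray(com) * vs + off0))

    shape = frag.shape
    all_lo, all_hi, all_vals = [], [], []
    for d, offset in enumerate(affs.neighborhood):
        src = tuple(slice(max(-o, 0), min(n - o, n)) for o, n in zip(offset, shape))
        dst = tuple(slice(max(o, 0), min(n + o, n)) for o, n in zip(offset, shape))
        a, b = frag[src], frag[dst]
        touching = (a > 0) & (b > 0) & (a != b)
        if not touching.any():
            continue
        pa = a[touching].astype(np.int64)
        pb = b[touching].astype(np.int64)
        all_lo.append(np.minimum(pa, pb))
        all_hi.append(np.maximum(pa, pb))
        all_vals.append(affs.data[d][src][touching].astype(np.float64))
    if all_lo:
        lo = np.concatenate(all_lo)
        hi = np.concatenate(all_hi)
        vals = np.concatenate(all_vals)
        key = lo * (int(frag.max()) + 1) + hi
        uniq, inverse = np.unique(key, return_inverse=True)
        sums = np.bincount(inverse, weights=vals)
        counts = np.bincount(inverse)
        base = int(frag.max()) + 1
        for k, s, c in zip(uniq.tolist(), sums.tolist(), counts.tolist()):
            u, v = divmod(k, base)
            rag.graph.add_edge(int(u), int(v), score=s / c, aff_sum=s,
                               pair_count=int(c))
    return rag


def agglomerate(rag: RegionAdjacencyGraph, merge_threshold: float) -> dict[int, int]:
    """Hierarchical merging in decreasing score order down to a threshold.

    The score between two clusters is the mean of the original face-pair
    affinities joining them (the pair-count-weighted mean of constituent
    edge scores), recomputed after every merge.  Ties break on the smaller,
    then larger, cluster-representative id, so results are reproducible.
    Returns fragment id -> cluster representative id.
    """
    parent = {int(n): int(n) for n in rag.graph.nodes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # neighbor maps: rep -> {rep: [aff_sum, pair_count]}
    nbrs: dict[int, dict[int, list[float]]] = {n: {} for n in parent}
    heap: list[tuple[float, int, int]] = []
    for u, v, data in rag.graph.edges(data=True):
        u, v = int(min(u, v)), int(max(u, v))
        nbrs[u][v] = [data["aff_sum"], data["pair_count"]]
        nbrs[v][u] = [data["aff_sum"], data["pair_count"]]
        heapq.heappush(heap, (-data["score"], u, v))

    while heap:
        neg_score, u, v = heapq.heappop(heap)
        score = -neg_score
        if score < merge_threshold:
            break
        if find(u) != u or find(v) != v or v not in nbrs[u]:
            continue  # stale entry
        s, c = nbrs[u][v]
        if abs(s / c - score) > 1e-12:
            continue  # score changed since this entry was pushed
        # merge v into u (u < v by construction of pushes)
        a, b = min(u, v), max(u, v)
        parent[b] = a
        na, nb = nbrs[a], nbrs[b]
        del na[b]
        del nb[a]
        for w, (s2, c2) in nb.items():
            del nbrs[w][b]
            if w in na:
                na[w][0] += s2
                na[w][1] += c2
            else:
                na[w] = [s2, c2]
            nbrs[w][a] = na[w]
            lo, hi = min(a, w), max(a, w)
            heapq.heappush(heap, (-(na[w][0] / na[w][1]), lo, hi))
        nbrs[b] = {}

    return {n: find(n) for n in parent}


def segment(affs: AffinityGrid, boundary_threshold: float, merge_threshold: float,
            seed_footprint: Sequence[int] = DEFAULT_SEED_FOOTPRINT) -> LabelVolume:
    """Watershed + RAG + agglomeration, relabeled to consecutive ids."""
    fragments = watershed_fragments(affs, boundary_threshold, seed_footprint)
    if not fragments.data.any():
        return fragments.labels
    rag = build_rag(fragments, affs)
    mapping = agglomerate(rag, merge_threshold)
    lut = np.zeros(int(fragments.data.max()) + 1, dtype=np.uint64)
    for frag_id, seg_id in mapping.items():
        lut[frag_id] = seg_id
    merged = lut[fragments.data.astype(np.int64)]
    out = relabel_consecutive(merged)
    return LabelVolume(out, affs.voxel_size, affs.offset)


def grid_search(affs: AffinityGrid, reference: LabelVolume,
                boundary_thresholds: Sequence[float],
                merge_thresholds: Sequence[float],
                metric: str = "voi_sum",
                score_fn: Callable[[LabelVolume, LabelVolume], float] | None = None,
                ) -> tuple[list[dict], dict]:
    """Evaluate ``segment`` over a parameter grid against a reference.

    ``metric`` is ``voi_sum`` (variation-of-information sum, bits) or
    ``mcm_per_object`` (split+merge edits per ground-truth object); lower
    is better.  Returns all rows sorted ascending by score plus the argmin
    row.  A custom ``score_fn(seg, reference)`` overrides the metric.
    """
    if not len(boundary_thresholds) or not len(merge_thresholds):
        raise ValueError("threshold grids must be non-empty")
    from . import evaluate as ev

    skeletons = None
    if score_fn is None and metric == "mcm_per_object":
        filtered = ev.filter_ground_truth(reference)
        skeletons = ev.skeletonize(filtered)
    elif score_fn is None and metric != "voi_sum":
        raise ValueError(f"unknown metric {metric!r}")

    rows = []
    for bt in boundary_thresholds:
        fragments = watershed_fragments(affs, bt)
        logger.info("grid: boundary %.2f -> %d fragments", bt,
                    len(np.unique(fragments.data)))
        rag = build_rag(fragments, affs) if fragments.data.any() else RegionAdjacencyGraph()
        for mt in merge_thresholds:
            if fragments.data.any():
                mapping = agglomerate(rag, mt)
                lut = np.zeros(int(fragments.data.max()) + 1, dtype=np.uint64)
                for frag_id, seg_id in mapping.items():
                    lut[frag_id] = seg_id
                seg = LabelVolume(relabel_consecutive(lut[fragments.data.astype(np.int64)]),
                                  affs.voxel_size, affs.offset)
                seg_of_frag = LabelVolume(lut[fragments.data.astype(np.int64)],
                                          affs.voxel_size, affs.offset)
            else:
                seg = fragments.labels
                seg_of_frag = seg
            if score_fn is not None:
                score = float(score_fn(seg, reference))
            elif metric == "voi_sum":
                score = float(ev.variation_of_information(seg, reference).sum)
            else:
                score = float(ev.min_cut_metric(
                    skeletons, seg_of_frag, rag, fragments).per_object)
            logger.info("grid: boundary %.2f merge %.2f -> %s %.4f",
                        bt, mt, metric, score)
            rows.append({"boundary_threshold": float(bt),
                         "merge_threshold": float(mt),
                         "score": score})
    rows.sort(key=lambda r: (r["score"], r["boundary_threshold"], r["merge_threshold"]))
    return rows, rows[0]
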
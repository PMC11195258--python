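"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorized / separable tricks of the package
code: descriptors are computed by direct per-voxel summation, affinities by
pairwise predicate evaluation, agglomeration by recomputing every
cluster-pair linkage from scratch at each step, and edit counts by
exhaustive search over cut sequences.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def gauss_kernel_sum(sigma: float, voxel: float) -> float:
    r = int(np.ceil(3.0 * sigma / voxel))
    i = np.arange(-r, r + 1, dtype=np.float64)
    return float(np.exp(-((i * voxel) ** 2) / (2.0 * sigma**2)).sum())


def brute_force_lsd(labels: np.ndarray, sigma, voxel_size, dimensionality: int = 3) -> np.ndarray:
    """Per-voxel direct summation over the 3-sigma box."""
    sigma = np.asarray(sigma, dtype=np.float64)
    voxel_size = np.asarray(voxel_size, dtype=np.float64)
    if dimensionality == 2:
        sig2, vs2 = sigma[-2:], voxel_size[-2:]
        sections = [
            _brute_force_lsd_nd(labels[z], sig2, vs2)[:, None]
            for z in range(labels.shape[0])
        ]
        return np.concatenate(sections, axis=1)
    return _brute_force_lsd_nd(labels, sigma, voxel_size)


def _brute_force_lsd_nd(labels: np.ndarray, sigma, voxel_size) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=np.float64)
    voxel_size = np.asarray(voxel_size, dtype=np.float64)
    d = labels.ndim
    n_corr = d * (d - 1) // 2
    n_channels = 2 * d + n_corr + 1
    radii = [int(np.ceil(3.0 * sigma[a] / voxel_size[a])) for a in range(d)]
    m_iso = float(np.prod([gauss_kernel_sum(sigma[a], voxel_size[a]) for a in range(d)]))
    out = np.zeros((n_channels,) + labels.shape, dtype=np.float64)
    shape = labels.shape
    for v in np.argwhere(labels > 0):
        lab = labels[tuple(v)]
        window = tuple(
            slice(max(v[a] - radii[a], 0), min(v[a] + radii[a] + 1, shape[a]))
            for a in range(d)
        )
        sub = labels[window]
        idx = np.argwhere(sub == lab)
        # absolute voxel indices of same-label voxels in the box
        base = np.array([window[a].start for a in range(d)])
        u = idx + base
        delta = (u - v[: d]) * voxel_size  # world-space offsets
        w = np.exp(-np.sum(delta**2 / (2.0 * sigma**2), axis=1))
        m = w.sum()
        mu = (w[:, None] * delta).sum(axis=0) / m
        centered = delta - mu
        cov = (w[:, None, None] * centered[:, :, None] * centered[:, None, :]).sum(axis=0) / m
        channels = []
        for a in range(d):
            channels.append(np.clip((mu[a] + sigma[a]) / (2 * sigma[a]), 0, 1))
        for a in range(d):
            channels.append(np.clip(cov[a, a] / sigma[a] ** 2, 0, 1))
        for a in range(d):
            for b in range(a + 1, d):
                denom = math.sqrt(max(cov[a, a], 0.0) * max(cov[b, b], 0.0))
                rho = cov[a, b] / denom if denom > 1e-12 else 0.0
                channels.append(np.clip((rho + 1) / 2, 0, 1))
        channels.append(min(m / m_iso, 1.0))
        out[(slice(None),) + tuple(v)] = channels
    return out


def brute_force_affinities(labels: np.ndarray, neighborhood) -> np.ndarray:
    """Same-nonzero-label predicate evaluated voxel pair by voxel pair."""
    D = len(neighborhood)
    out = np.zeros((D,) + labels.shape, dtype=np.float32)
    for d, off in enumerate(neighborhood):
        for p in itertools.product(*[range(n) for n in labels.shape]):
            q = tuple(p[a] + off[a] for a in range(3))
            if any(q[a] < 0 or q[a] >= labels.shape[a] for a in range(3)):
                continue
            if labels[p] > 0 and labels[p] == labels[q]:
                out[(d,) + p] = 1.0
    return out


def brute_force_agglomerate(nodes, edges, merge_threshold: float):
    """Hierarchical agglomeration recomputing every cluster-pair mean per step.

    ``edges`` maps frozenset({u, v}) -> (score_sum, pair_count) of original
    face-pair affinities.  Returns node -> cluster representative.
    """
    clusters = {n: frozenset([n]) for n in nodes}

    def cluster_pairs():
        uniq = {}
        for c in clusters.values():
            uniq[min(c)] = c
        return list(uniq.values())

    while True:
        best = None
        for ca, cb in itertools.combinations(cluster_pairs(), 2):
            s, cnt = 0.0, 0
            for u in ca:
                for v in cb:
                    e = frozenset((u, v))
                    if e in edges:
                        ssum, n = edges[e]
                        s += ssum
                        cnt += n
            if cnt == 0:
                continue
            score = s / cnt
            key = (-score, min(min(ca), min(cb)), max(min(ca), min(cb)))
            if best is None or key < best[0]:
                best = (key, ca, cb, score)
        if best is None or best[3] < merge_threshold:
            break
        _, ca, cb, _ = best
        merged = ca | cb
        for n in merged:
            clusters[n] = merged
    return {n: min(clusters[n]) for n in nodes}


def _components(nodes, edges):
    """Connected components by plain DFS; edges is an iterable of 2-sets."""
    adj = {n: set() for n in nodes}
    for e in edges:
        u, v = tuple(e)
        if u in adj and v in adj:
            adj[u].add(v)
            adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(adj[n] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def _pair_connected(nodes, edges, set_a, set_b):
    for comp in _components(nodes, edges):
        if comp & set_a and comp & set_b:
            return True
    return False


def exhaustive_edit_count(skeleton_nodes, skeleton_edges, node_segment,
                          node_fragment, rag_edges, frag_segment):
    """Exhaustive split/merge edit count on a tiny instance.

    ``skeleton_nodes``: dict sk_id -> list of node ids.
    ``skeleton_edges``: dict sk_id -> list of (a, b).
    ``node_segment`` / ``node_fragment``: node id -> segment / fragment id.
    ``rag_edges``: set of frozenset({f, g}) fragment adjacencies.
    ``frag_segment``: fragment id -> segment id.

    Split edits: per skeleton, number of same-segment connected components
    minus one (background nodes dropped).  Merge edits: per segment hosting
    >= 2 skeletons, the minimum number of cut operations found by breadth-
    first search over edge-removal states, where one operation removes any
    minimum-size edge subset disconnecting one still-connected skeleton
    pair (minimum cuts enumerated by brute-force subset search).
    """
    splits = 0
    for sk, nodes_list in skeleton_nodes.items():
        nodes_in = [n for n in nodes_list if node_segment[n] != 0]
        if not nodes_in:
            continue
        kept = [frozenset((a, b)) for a, b in skeleton_edges[sk]
                if a in nodes_in and b in nodes_in
                and node_segment[a] == node_segment[b]]
        splits += len(_components(nodes_in, kept)) - 1

    merges = 0
    segments = sorted({s for s in node_segment.values() if s != 0})
    for seg in segments:
        sk_frags = {}
        for sk, nodes_list in skeleton_nodes.items():
            frags = {node_fragment[n] for n in nodes_list
                     if node_segment[n] == seg}
            if frags:
                sk_frags[sk] = frags
        if len(sk_frags) < 2:
            continue
        seg_frag_ids = {f for f, s in frag_segment.items() if s == seg}
        edges = frozenset(e for e in rag_edges
                          if set(e) <= seg_frag_ids)
        fragsets = [sk_frags[k] for k in sorted(sk_frags)]
        merges += _min_cut_operations_bfs(seg_frag_ids, edges, fragsets)
    return splits, merges


def _min_cut_operations_bfs(nodes, edges, fragsets):
    """Minimum number of cut operations, BFS over remaining-edge states."""
    def open_pairs(es):
        return [(i, j) for i, j in itertools.combinations(range(len(fragsets)), 2)
                if not (fragsets[i] & fragsets[j])
                and _pair_connected(nodes, es, fragsets[i], fragsets[j])]

    start = frozenset(edges)
    if not open_pairs(start):
        return 0
    frontier = {start}
    ops = 0
    seen = {start}
    while frontier:
        ops += 1
        nxt = set()
        for state in frontier:
            for i, j in open_pairs(state):
                # minimum cut size between the pair by subset enumeration
                state_list = sorted(state, key=sorted)
                found_k = None
                for k in range(1, len(state_list) + 1):
                    cuts = [c for c in itertools.combinations(state_list, k)
                            if not _pair_connected(nodes, state - set(c),
                                                   fragsets[i], fragsets[j])]
                    if cuts:
                        found_k = k
                        break
                if found_k is None:
                    continue
                for cut in cuts:
                    new_state = state - set(cut)
                    if new_state in seen:
                        continue
                    if not open_pairs(new_state):
                        return ops
                    seen.add(new_state)
                    nxt.add(new_state)
        frontier = nxt
        if ops > 10:  # safety for malformed fixtures
            return ops
    return ops


def brute_force_voi(seg: np.ndarray, gt: np.ndarray):
    """Conditional entropies in bits over gt-foreground voxels, by histogram."""
    fg = gt > 0
    s, g = seg[fg].ravel(), gt[fg].ravel()
    n = s.size
    pairs = {}
    for a, b in zip(s.tolist(), g.tolist()):
        pairs[(a, b)] = pairs.get((a, b), 0) + 1
    ps, pg = {}, {}
    for (a, b), c in pairs.items():
        ps[a] = ps.get(a, 0) + c
        pg[b] = pg.get(b, 0) + c
    h_sg = 0.0  # H(seg | gt)
    h_gs = 0.0  # H(gt | seg)
    for (a, b), c in pairs.items():
        p = c / n
        h_sg -= p * math.log2(c / pg[b])
        h_gs -= p * math.log2(c / ps[a])
    return h_sg, h_gs
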
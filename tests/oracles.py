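"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def brute_force_dbscan(coords, eps, min_pts):
    """O(n^2) DBSCAN: explicit neighborhood enumeration + BFS over core points.

    Same conventions as the package implementation (self-inclusive MinPts,
    border point joins the cluster of the first core neighbor in scan order),
    but built from a full distance matrix with no spatial index.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    neighbor_sets = [np.nonzero(d[i] <= eps)[0].tolist() for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbor_sets]
    labels = [-1] * n
    cluster = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != -1:
            continue
        labels[seed] = cluster
        frontier = [seed]
        while frontier:
            nxt = []
            for p in frontier:
                for q in neighbor_sets[p]:
                    if labels[q] == -1:
                        labels[q] = cluster
                        if core[q]:
                            nxt.append(q)
            frontier = nxt
        cluster += 1
    return np.array(labels)


def labels_equivalent(a, b):
    """True iff two labelings agree up to cluster renumbering (noise = -1
    must match exactly)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not ((a == -1) == (b == -1)).all():
        return False
    mapping = {}
    reverse = {}
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if mapping.setdefault(la, lb) != lb:
            return False
        if reverse.setdefault(lb, la) != la:
            return False
    return True


def brute_force_merge(coords, frames, radius):
    """Chain-enumeration merge oracle for tiny instances (single channel).

    Links records in consecutive frames greedily by increasing distance
    (ties by record index), collapses linked chains transitively, iterates to
    a fixed point.  Returns (positions, frames) sorted canonically; each
    position is the unweighted mean of the ORIGINAL records of its chain.
    """
    coords = np.asarray(coords, dtype=float)
    groups = [[i] for i in range(len(coords))]
    g_frames = list(frames)
    g_pos = [coords[i].copy() for i in range(len(coords))]

    while True:
        links = []
        order = sorted(range(len(groups)), key=lambda k: (g_frames[k], *g_pos[k]))
        for f in sorted(set(g_frames)):
            src = [k for k in order if g_frames[k] == f]
            dst = [k for k in order if g_frames[k] == f + 1]
            cands = []
            for i, ki in enumerate(src):
                for j, kj in enumerate(dst):
                    dist = float(np.linalg.norm(g_pos[ki] - g_pos[kj]))
                    if dist <= radius:
                        cands.append((dist, i, j, ki, kj))
            cands.sort(key=lambda t: (t[0], t[1], t[2]))
            used_i, used_j = set(), set()
            for dist, i, j, ki, kj in cands:
                if i in used_i or j in used_j:
                    continue
                used_i.add(i)
                used_j.add(j)
                links.append((ki, kj))
        if not links:
            break
        parent = list(range(len(groups)))

        def find(k):
            while parent[k] != k:
                k = parent[k]
            return k

        for ki, kj in links:
            ri, rj = find(ki), find(kj)
            if ri != rj:
                parent[rj] = ri
        merged = {}
        for k in range(len(groups)):
            merged.setdefault(find(k), []).extend(groups[k])
        groups = [sorted(v) for v in merged.values()]
        g_frames = [min(frames[i] for i in g) for g in groups]
        g_pos = [coords[g].mean(axis=0) for g in groups]

    out = sorted(zip(g_pos, g_frames), key=lambda t: (t[1], t[0][0], t[0][1], t[0][2]))
    return np.array([p for p, _ in out]), np.array([f for _, f in out])


def per_base_bin_means(intervals, bin_size, n_bins):
    """Expand bedGraph intervals to a per-base array and average per bin."""
    arr = np.zeros(n_bins * bin_size)
    for start, end, value in intervals:
        arr[start:end] += value
    return arr.reshape(n_bins, bin_size).mean(axis=1)


def smoothed_defined_series(values, window):
    """Centered moving average over the nearest `window` defined entries,
    skipping NaNs; NaN entries stay NaN."""
    values = np.asarray(values, dtype=float)
    out = np.full(len(values), np.nan)
    defined = np.nonzero(~np.isnan(values))[0]
    half = window // 2
    for rank, idx in enumerate(defined):
        lo = max(rank - half, 0)
        hi = min(rank + half, len(defined) - 1)
        out[idx] = values[defined[lo : hi + 1]].mean()
    return out
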
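"""Independent brute-force oracles used by the test suite only.

Each oracle re-derives a quantity by exhaustive enumeration or a naive
algorithm, deliberately sharing no code with the implementation it checks.
"""

from itertools import combinations

import numpy as np


def brute_force_ckmeans(values, k):
    """Globally optimal contiguous k-partition by exhaustive enumeration.

    Enumerates all C(n-1, k-1) placements of cluster boundaries on the
    sorted values and returns (total within-ss, cluster sizes).
    """
    xs = np.sort(np.asarray(values, dtype=float))
    n = len(xs)
    best = (np.inf, None)
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        ss = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = xs[a:b]
            ss += ((seg - seg.mean()) ** 2).sum()
        if ss < best[0] - 1e-12:
            best = (ss, tuple(b - a for a, b in zip(bounds[:-1], bounds[1:])))
    return best


def naive_agglomerate(values, linkage):
    """O(n^3) agglomerative clustering of 1D values.

    Cluster distances are recomputed from raw points at every merge:
    single = min pairwise |xi - xj|, complete = max, average = mean, and
    ward = the within-ss increase of the merge.  Returns the list of
    partitions (frozenset of frozensets of indices) after each merge.
    """
    x = np.asarray(values, dtype=float)
    clusters = [frozenset([i]) for i in range(len(x))]
    partitions = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i, j in combinations(range(len(clusters)), 2):
            a = np.array([x[m] for m in clusters[i]])
            b = np.array([x[m] for m in clusters[j]])
            d = np.abs(a[:, None] - b[None, :])
            if linkage == "single":
                dist = d.min()
            elif linkage == "complete":
                dist = d.max()
            elif linkage == "average":
                dist = d.mean()
            else:  # ward: within-ss increase of merging the two clusters
                merged = np.concatenate([a, b])
                dist = (
                    ((merged - merged.mean()) ** 2).sum()
                    - ((a - a.mean()) ** 2).sum()
                    - ((b - b.mean()) ** 2).sum()
                )
            if dist < best[0] - 1e-12:
                best = (dist, (i, j))
        i, j = best[1]
        merged = clusters[i] | clusters[j]
        clusters = [c for m, c in enumerate(clusters) if m not in (i, j)] + [merged]
        partitions.append(frozenset(clusters))
    return partitions


def brute_force_feret(coords):
    """Max pairwise distance over all pixel corners of a region (no hull)."""
    coords = np.asarray(coords, dtype=float)
    offsets = np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])
    pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def half_plane_inside(vertices, point):
    """Convex-polygon membership via edge half-planes (CCW vertices)."""
    vertices = np.asarray(vertices, dtype=float)
    for i in range(len(vertices)):
        a = vertices[i]
        b = vertices[(i + 1) % len(vertices)]
        cross = (b[0] - a[0]) * (point[1] - a[1]) - (b[1] - a[1]) * (point[0] - a[0])
        if cross < -1e-12:
            return False
    return True
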
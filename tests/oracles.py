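"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — plain loops, no spatial indexes,
no library clustering — so that agreement with the package is meaningful.
"""

from __future__ import annotations

import numpy as np


def brute_point_in_union(p, centers, radii, tol=0.0) -> bool:
    p = np.asarray(p, float)
    for c, r in zip(centers, radii):
        if np.linalg.norm(p - np.asarray(c, float)) <= r + tol:
            return True
    return False


def brute_jaccard(centers_a, radii_a, centers_b, radii_b, tol=0.0) -> float:
    a = sum(brute_point_in_union(p, centers_b, radii_b, tol) for p in centers_a)
    b = sum(brute_point_in_union(p, centers_a, radii_a, tol) for p in centers_b)
    return (a + b) / (len(centers_a) + len(centers_b))


def brute_dbscan(points, eps, min_pts):
    """Classical DBSCAN by breadth-first expansion in index order.

    Returns (labels, core_mask): labels[i] = cluster id (0-based) or -1
    for noise.  Neighbourhoods are self-inclusive.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    neigh = [
        [j for j in range(n) if np.linalg.norm(pts[i] - pts[j]) <= eps]
        for i in range(n)
    ]
    core = np.array([len(neigh[i]) >= min_pts for i in range(n)])
    labels = np.full(n, -2)  # -2 unvisited, -1 noise
    cid = 0
    for i in range(n):
        if labels[i] != -2 or not core[i]:
            continue
        queue = [i]
        labels[i] = cid
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in neigh[j]:
                if labels[k] in (-2, -1):
                    labels[k] = cid
                    queue.append(k)
        cid += 1
    labels[labels == -2] = -1
    return labels, core


def greedy_match_trace(values):
    """Reference repetition removal: repeatedly keep the largest remaining
    nonzero value (ties: lowest row, then lowest column) and zero the rest
    of its row and column."""
    v = np.array(values, float)
    out = np.zeros_like(v)
    active = v.copy()
    while active.max(initial=0.0) > 0:
        best = None
        for i in range(active.shape[0]):
            for j in range(active.shape[1]):
                if active[i, j] > 0 and (best is None or active[i, j] > active[best]):
                    best = (i, j)
        i, j = best
        out[i, j] = v[i, j]
        active[i, :] = 0.0
        active[:, j] = 0.0
    return out
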
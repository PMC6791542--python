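"""Classification of detections from an overlap matrix.

A predicted cavity with at least one nonzero overlap is a true positive;
an all-zero row is a false positive; an all-zero column is a false
negative (a ground-truth cavity nobody found).  Repetition removal turns
many-to-many overlaps into a one-to-one matching by greedily keeping the
largest remaining value and zeroing the rest of its row and column; this
can only lower TP and raise FP/FN.

True negatives — putative cavity regions absent from both ground truth and
prediction — cannot be read off the matrix; an optional geometric estimate
samples the space inside the protein's convex hull not covered by any atom
or pseudo-atom sphere and clusters it with DBSCAN.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .cluster import ClusteringParams, cluster_pseudo_atoms
from .core import (
    Cavity,
    CavitySet,
    CavityType,
    ClassificationCounts,
    OverlapMatrix,
    PseudoAtom,
)

__all__ = [
    "remove_repetitions",
    "classify",
    "matched_columns",
    "estimate_true_negatives",
]


def remove_repetitions(M: OverlapMatrix) -> OverlapMatrix:
    """One-to-one matching by greedy best-overlap retention.

    Repeatedly select the largest remaining nonzero value, keep it, and
    zero every other entry in its row and column.  Ties break by lower row
    index, then lower column index — deterministic and idempotent.  Kept
    values are the original values; zeros stay zero.
    """
    values = M.values.copy()
    m, n = values.shape
    out = np.zeros_like(values)
    rows_free = np.ones(m, dtype=bool)
    cols_free = np.ones(n, dtype=bool)
    while True:
        masked = np.where(np.outer(rows_free, cols_free), values, 0.0)
        if masked.size == 0 or masked.max() <= 0:
            break
        # argmax on the flattened array honours (row, col) index tie-break
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        out[i, j] = values[i, j]
        rows_free[i] = False
        cols_free[j] = False
    return OverlapMatrix(
        protein_id=M.protein_id,
        row_ids=list(M.row_ids),
        col_ids=list(M.col_ids),
        values=out,
        repetitions_removed=True,
    )


def classify(M: OverlapMatrix, min_overlap: float = 0.0) -> ClassificationCounts:
    """TP/FP/FN from an overlap matrix (with or without repetitions).

    A hit is any overlap strictly above ``min_overlap`` (default 0: any
    nonzero Jaccard counts, i.e. a nonempty intersection).  TP = rows with
    a hit, FP = rows without, FN = columns without.  TN is left unset.
    """
    hits = M.values > min_overlap
    row_hit = hits.any(axis=1)
    col_hit = hits.any(axis=0)
    return ClassificationCounts(
        tp=int(row_hit.sum()),
        fp=int((~row_hit).sum()),
        fn=int((~col_hit).sum()),
    )


def matched_columns(M: OverlapMatrix, min_overlap: float = 0.0) -> int:
    """Number of ground-truth cavities with at least one hit (complements
    FN; with repetitions kept this may differ from TP)."""
    return int((M.values > min_overlap).any(axis=0).sum())


def estimate_true_negatives(
    protein_atoms: Sequence[PseudoAtom],
    truth: Optional[CavitySet],
    predicted: Optional[CavitySet],
    grid_spacing: float = 1.0,
    eps: Optional[float] = None,
    min_pts: int = 4,
) -> tuple[int, list[Cavity]]:
    """Estimate undetected cavity regions (true negatives) geometrically.

    Procedure: (i) convex hull of the protein atom centers; (ii) union of
    all spheres — protein atoms plus the pseudo-atoms of both cavity sets;
    (iii) grid-sample the hull interior at ``grid_spacing`` and keep points
    outside the union; (iv) DBSCAN the survivors, discarding noise.  Each
    cluster is returned as a NOTYPE cavity of grid-point spheres with
    radius ``grid_spacing / 2``.

    ``eps`` defaults to 2 × grid_spacing so diagonal grid neighbours
    connect.  Raises ``ValueError`` when the hull is undefined (< 4
    non-coplanar atom centers).

    Returns ``(cluster_count, clusters)``.  The estimate is excluded from
    precision/recall/F-score, which do not depend on true negatives.
    """
    if not protein_atoms:
        raise ValueError("protein_atoms must be non-empty")
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if eps is None:
        eps = 2.0 * grid_spacing

    centers = np.array([a.center for a in protein_atoms], dtype=float)
    try:
        hull = ConvexHull(centers)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"convex hull undefined: {exc}") from exc
    del hull  # existence check; containment uses Delaunay below
    tri = Delaunay(centers)

    # union of every sphere that is "occupied": protein + both cavity sets
    spheres = [(np.array(a.center), a.radius) for a in protein_atoms]
    for cavset in (truth, predicted):
        if cavset is not None:
            for cav in cavset:
                spheres.extend((np.array(a.center), a.radius) for a in cav.atoms)
    sphere_centers = np.array([s[0] for s in spheres])
    sphere_radii = np.array([s[1] for s in spheres])

    lo = centers.min(axis=0)
    hi = centers.max(axis=0)
    axes = [np.arange(lo[k], hi[k] + 0.5 * grid_spacing, grid_spacing) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    inside_hull = tri.find_simplex(grid) >= 0
    grid = grid[inside_hull]
    if grid.size == 0:
        return 0, []

    tree = cKDTree(sphere_centers)
    rmax = float(sphere_radii.max())
    covered = np.zeros(len(grid), dtype=bool)
    for g, idx in zip(range(len(grid)), tree.query_ball_point(grid, r=rmax)):
        if idx:
            idx = np.asarray(idx)
            d = np.linalg.norm(sphere_centers[idx] - grid[g], axis=1)
            if np.any(d <= sphere_radii[idx]):
                covered[g] = True
    free = grid[~covered]
    if len(free) == 0:
        return 0, []

    free_atoms = [PseudoAtom(tuple(p), grid_spacing / 2.0) for p in free]
    cavities, _noise = cluster_pseudo_atoms(
        free_atoms, ClusteringParams(eps=eps, min_pts=min_pts)
    )
    cavities = [
        Cavity(id=f"tn{i + 1}", type=CavityType.NOTYPE, atoms=c.atoms)
        for i, c in enumerate(cavities)
    ]
    return len(cavities), cavities
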
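"""Jaccard overlap between sphere-cluster cavities and per-protein
overlap matrices.

The similarity between a predicted cavity c and a ground-truth cavity C is
a center-counting Jaccard index: with A = number of pseudo-atom centers of
c inside the sphere union of C and B = number of centers of C inside the
union of c,

    J(c, C) = (A + B) / (|c| + |C|)

which is symmetric, lies in [0, 1], equals 1 for congruent clusters and 0
for disjoint ones.  Duplicate centers count with multiplicity.  A k-d tree
accelerates the center-in-union test; it is exactly equivalent to the
brute-force loop over spheres.
"""

from __future__ import annotations

import csv
from typing import IO

import numpy as np
from scipy.spatial import cKDTree

from .core import DEFAULT_TOL, Cavity, CavitySet, OverlapMatrix

__all__ = [
    "jaccard",
    "coverage_of_ground_truth",
    "build_overlap_matrix",
    "write_overlap_csv",
]


def _centers_inside(points: np.ndarray, cavity: Cavity, tol: float) -> int:
    """Count rows of ``points`` lying inside the sphere union of ``cavity``.

    Tree-accelerated but decision-identical to testing every sphere:
    candidate neighbours are gathered within max radius + tol, then each
    candidate is checked against the individual sphere radius with the same
    inclusive comparison the brute-force loop uses.
    """
    centers = cavity.centers()
    radii = cavity.radii()
    rmax = float(radii.max())
    tree = cKDTree(centers)
    inside = 0
    neighbourhoods = tree.query_ball_point(points, r=rmax + tol)
    for p, idx in zip(points, neighbourhoods):
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.linalg.norm(centers[idx] - p, axis=1)
        if np.any(d <= radii[idx] + tol):
            inside += 1
    return inside


def jaccard(c: Cavity, C: Cavity, tol: float = DEFAULT_TOL) -> float:
    """Center-counting Jaccard similarity between two cavities, in [0, 1].

    Parameters
    ----------
    c, C : Cavity
        Predicted and ground-truth cavity (the measure is symmetric).
    tol : float
        Inclusion tolerance in Å (boundary inclusive).

    Returns
    -------
    float
        ``(A + B) / (|c| + |C|)`` with A, B the mutual center-in-union
        counts.  1.0 iff every center of each cluster lies inside the
        other; 0.0 iff no center of either lies inside the other.
    """
    if not c.atoms or not C.atoms:
        raise ValueError("jaccard undefined for empty cavities")
    a = _centers_inside(c.centers(), C, tol)
    b = _centers_inside(C.centers(), c, tol)
    return (a + b) / (len(c) + len(C))


def coverage_of_ground_truth(
    c: Cavity, C: Cavity, tol: float = DEFAULT_TOL
) -> float:
    """Fraction of ground-truth centers of ``C`` lying inside predicted
    cavity ``c`` — a directional "how much of the true cavity was found"
    measure (not symmetric)."""
    if not C.atoms:
        raise ValueError("coverage undefined for empty ground-truth cavity")
    return _centers_inside(C.centers(), c, tol) / len(C)


def build_overlap_matrix(
    predicted: CavitySet, truth: CavitySet, tol: float = DEFAULT_TOL
) -> OverlapMatrix:
    """Jaccard matrix for one protein: rows = predicted cavities, columns =
    ground-truth cavities, order preserved from both sets.

    Raises ``ValueError`` if the two sets name different proteins.
    """
    if predicted.protein_id != truth.protein_id:
        raise ValueError(
            f"protein mismatch: {predicted.protein_id!r} vs {truth.protein_id!r}"
        )
    m, n = len(predicted), len(truth)
    values = np.zeros((m, n), dtype=float)
    for i, c in enumerate(predicted):
        for j, C in enumerate(truth):
            values[i, j] = jaccard(c, C, tol)
    return OverlapMatrix(
        protein_id=predicted.protein_id,
        row_ids=predicted.cavity_ids(),
        col_ids=truth.cavity_ids(),
        values=values,
        repetitions_removed=False,
    )


def write_overlap_csv(matrix: OverlapMatrix, stream: IO[str]) -> None:
    """CSV export: header row of ground-truth ids, first column of
    predicted ids, cells with 4 decimals."""
    w = csv.writer(stream, lineterminator="\n")
    w.writerow([""] + list(matrix.col_ids))
    for rid, row in zip(matrix.row_ids, matrix.values):
        w.writerow([rid] + [f"{v:.4f}" for v in row])
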
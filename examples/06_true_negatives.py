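"""Geometric true-negative estimation on a hollow cube.

True negatives — cavity-sized regions absent from both ground truth and
prediction — cannot be read off the overlap matrix.  The estimate grid-
samples the protein's convex hull, removes everything covered by atom or
pseudo-atom spheres, and clusters what is left with DBSCAN.
"""

from cavitybench import (
    Cavity,
    CavitySet,
    CavityType,
    PseudoAtom,
    estimate_true_negatives,
)

# 8 corner "atoms" of a cube of side 10 Å: the hull encloses an interior
# void no sphere covers
corners = [(x, y, z) for x in (0, 10) for y in (0, 10) for z in (0, 10)]
protein = [PseudoAtom(c, 1.0) for c in corners]

count, voids = estimate_true_negatives(
    protein, truth=None, predicted=None, grid_spacing=1.0, eps=1.5, min_pts=4
)
print(f"empty hull: {count} undetected cavity cluster(s), "
      f"{len(voids[0])} grid spheres in the largest")

filler = CavitySet(
    "cube", "truth",
    [Cavity("fill", CavityType.NOTYPE, [PseudoAtom((5, 5, 5), 9.0)])],
)
count_filled, _ = estimate_true_negatives(
    protein, truth=filler, predicted=None, grid_spacing=1.0, eps=1.5, min_pts=4
)
print(f"void covered by a ground-truth cavity: {count_filled} cluster(s)")
# 1 cluster for the hollow cube, 0 once a known cavity fills the void —
# the estimate only reports space unaccounted for by either side.
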
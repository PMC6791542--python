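"""Jaccard overlap between two sphere-cluster cavities.

Builds a tiny predicted cavity and ground-truth cavity, prints their
center-counting Jaccard similarity, the directional coverage of the
ground truth, and the per-protein overlap matrix as CSV.
"""

import sys

from cavitybench import (
    Cavity,
    CavitySet,
    CavityType,
    PseudoAtom,
    build_overlap_matrix,
    coverage_of_ground_truth,
    jaccard,
    write_overlap_csv,
)

predicted = Cavity(
    id="c1", type=CavityType.NOTYPE,
    atoms=[PseudoAtom((0, 0, 0), 1.5), PseudoAtom((1, 0, 0), 1.5)],
)
truth = Cavity(
    id="C1", type=CavityType.CLEFT,
    atoms=[PseudoAtom((1, 0, 0), 1.5), PseudoAtom((5, 0, 0), 1.0)],
)

j = jaccard(predicted, truth)
cov = coverage_of_ground_truth(predicted, truth)
print(f"Jaccard(c1, C1) = {j:.4f}")
print(f"coverage of C1 by c1 = {cov:.4f}")
# J = 0.75: both centers of c1 are inside C1's sphere union and one of
# C1's two centers is inside c1, so (2+1)/(2+2).  Coverage = 0.5: c1
# reaches one of C1's two centers.

M = build_overlap_matrix(
    CavitySet("demo", "method", [predicted]),
    CavitySet("demo", "truth", [truth]),
)
print("\noverlap matrix (rows = predicted, columns = ground truth):")
write_overlap_csv(M, sys.stdout)
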
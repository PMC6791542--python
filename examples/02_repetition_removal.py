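"""Repetition removal and its effect on TP/FP/FN.

A predicted cavity overlapping several ground-truth cavities (or vice
versa) is a repetition.  Greedy best-overlap retention turns the matrix
into a one-to-one matching — which can only lower true positives and
raise false positives/negatives.
"""

import numpy as np

from cavitybench import OverlapMatrix, classify, remove_repetitions

M = OverlapMatrix(
    protein_id="demo",
    row_ids=["c1", "c2", "c3"],
    col_ids=["C1", "C2"],
    values=np.array([[0.7, 0.2], [0.3, 0.0], [0.0, 0.1]]),
)

before = classify(M)
out = remove_repetitions(M)
after = classify(out)

print("matrix with repetitions:\n", M.values)
print(f"counts: TP={before.tp} FP={before.fp} FN={before.fn}")
print("\nmatrix after repetition removal:\n", out.values)
print(f"counts: TP={after.tp} FP={after.fp} FN={after.fn}")
# c1 keeps its best match C1 (0.70), which forces (c2, C1) to zero:
# c2's row becomes empty and turns into a new false positive, so TP
# drops from 3 to 2 and FP rises from 0 to 1.
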
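"""One-call evaluation of a predicted cavity set against ground truth."""

from __future__ import annotations

from dataclasses import dataclass

from .core import CavitySet, ClassificationCounts, OverlapMatrix
from .core import DEFAULT_TOL
from .matching import classify, remove_repetitions
from .overlap import build_overlap_matrix

__all__ = ["EvaluationResult", "evaluate_pair"]


@dataclass
class EvaluationResult:
    """Overlap matrices and counts for one protein, both scenarios."""

    protein_id: str
    matrix: OverlapMatrix
    matrix_no_repetitions: OverlapMatrix
    counts: ClassificationCounts
    counts_no_repetitions: ClassificationCounts


def evaluate_pair(
    predicted: CavitySet,
    truth: CavitySet,
    tol: float = DEFAULT_TOL,
    min_overlap: float = 0.0,
) -> EvaluationResult:
    """Build the overlap matrix for one protein and classify it with and
    without repetition removal.

    ``min_overlap`` raises the hit threshold above "any nonzero Jaccard";
    it is applied by zeroing sub-threshold entries before matching, so
    both scenarios see the same filtered matrix.
    """
    matrix = build_overlap_matrix(predicted, truth, tol)
    if min_overlap > 0:
        filtered = matrix.values.copy()
        filtered[filtered <= min_overlap] = 0.0
        matrix = OverlapMatrix(
            protein_id=matrix.protein_id,
            row_ids=matrix.row_ids,
            col_ids=matrix.col_ids,
            values=filtered,
            repetitions_removed=False,
        )
    no_reps = remove_repetitions(matrix)
    return EvaluationResult(
        protein_id=matrix.protein_id,
        matrix=matrix,
        matrix_no_repetitions=no_reps,
        counts=classify(matrix),
        counts_no_repetitions=classify(no_reps),
    )
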
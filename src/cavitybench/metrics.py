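"""Precision, recall and F-score from classification counts.

    p = TP / (TP + FP)        r = TP / (TP + FN)
    F = 2·TP / (2·TP + FP + FN)

F is computed from the counts directly — the harmonic mean of the
full-precision p and r, never of rounded values.  A zero denominator
yields None ("NA" in reports), not 0 and not an exception: a protein with
no predicted cavities has undefined precision.

Aggregation across proteins or protein groups (apo/holo) is micro-
averaging: counts are summed element-wise and metrics computed once on
the sums.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from .core import ClassificationCounts, PerformanceMetrics

__all__ = [
    "precision",
    "recall",
    "fscore",
    "metrics",
    "aggregate",
    "render_value",
    "render_metrics_table",
]


def precision(counts: ClassificationCounts) -> Optional[float]:
    """Fraction of predicted cavities that match a ground-truth cavity;
    None when nothing was predicted."""
    d = counts.tp + counts.fp
    return counts.tp / d if d else None


def recall(counts: ClassificationCounts) -> Optional[float]:
    """Fraction of ground-truth cavities that were detected (sensitivity,
    true-positive rate); None when there are no positives."""
    d = counts.tp + counts.fn
    return counts.tp / d if d else None


def fscore(counts: ClassificationCounts) -> Optional[float]:
    """Harmonic mean of precision and recall, computed from the raw counts
    as 2·TP / (2·TP + FP + FN); None when the denominator is zero."""
    d = 2 * counts.tp + counts.fp + counts.fn
    return 2 * counts.tp / d if d else None


def metrics(counts: ClassificationCounts) -> PerformanceMetrics:
    return PerformanceMetrics(
        precision=precision(counts),
        recall=recall(counts),
        fscore=fscore(counts),
    )


def aggregate(counts_list: Iterable[ClassificationCounts]) -> ClassificationCounts:
    """Micro-averaging sum: element-wise TP/FP/FN totals (TN only when
    every input carries one).  Empty input gives all zeros."""
    items = list(counts_list)
    tn: Optional[int]
    if items and all(c.tn is not None for c in items):
        tn = sum(c.tn for c in items)  # type: ignore[misc]
    else:
        tn = None
    return ClassificationCounts(
        tp=sum(c.tp for c in items),
        fp=sum(c.fp for c in items),
        fn=sum(c.fn for c in items),
        tn=tn,
    )


def render_value(v: Optional[float], decimals: int = 2) -> str:
    """Format a metric for a report: round half away from zero to the
    given decimals; None renders as "NA"."""
    if v is None:
        return "NA"
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))


def render_metrics_table(
    rows: list[tuple[str, dict[str, ClassificationCounts]]],
    groups: list[str],
) -> str:
    """Aligned plain-text table: one row per method, per group the TP, FP,
    FN counts and p, r, F at 2 decimals ("NA" when undefined)."""
    header = ["Method"]
    for g in groups:
        header += [f"{g}:TP", f"{g}:FP", f"{g}:FN", f"{g}:p", f"{g}:r", f"{g}:F"]
    lines = [header]
    for method, per_group in rows:
        line = [method]
        for g in groups:
            c = per_group[g]
            m = metrics(c)
            line += [
                str(c.tp),
                str(c.fp),
                str(c.fn),
                render_value(m.precision),
                render_value(m.recall),
                render_value(m.fscore),
            ]
        lines.append(line)
    widths = [max(len(row[i]) for row in lines) for i in range(len(header))]
    return "\n".join(
        "  ".join(cell.rjust(w) for cell, w in zip(row, widths)) for row in lines
    )
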
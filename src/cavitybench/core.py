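"""Domain model for cavity benchmarking.

A protein cavity (cleft, tunnel, pore, or untyped detection) is represented
as a cluster of spheres ("pseudo-atoms"), each with a center and radius in
Ångströms.  A :class:`CavitySet` holds all cavities of one protein from one
source — either a ground-truth dataset or a cavity detection method.  The
benchmark compares a predicted set against a ground-truth set through a
per-protein :class:`OverlapMatrix` of Jaccard values, from which
:class:`ClassificationCounts` (TP/FP/FN, optionally TN) and
:class:`PerformanceMetrics` (precision, recall, F-score) are derived.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PseudoAtom",
    "CavityType",
    "Cavity",
    "CavitySet",
    "OverlapMatrix",
    "ClassificationCounts",
    "PerformanceMetrics",
    "point_in_cavity",
    "DEFAULT_TOL",
]

#: Default inclusion tolerance (Å).  Boundary points at exactly one radius
#: from a sphere center are inside; the tiny slack makes that decision
#: stable across floating-point summation orders.
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class PseudoAtom:
    """A sphere representing one dummy/hetero-atom of a cavity.

    Parameters
    ----------
    center : sequence of 3 floats
        Cartesian coordinates in Å.
    radius : float
        Sphere radius in Å; must be positive.
    serial : int, optional
        Record serial number from the source file, if any.
    """

    center: tuple[float, float, float]
    radius: float
    serial: Optional[int] = None

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.center)
        if len(c) != 3:
            raise ValueError(f"center must have 3 coordinates, got {len(c)}")
        if not all(math.isfinite(v) for v in c):
            raise ValueError(f"non-finite coordinates: {c}")
        r = float(self.radius)
        if not (math.isfinite(r) and r > 0):
            raise ValueError(f"radius must be positive and finite, got {self.radius}")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "radius", r)


class CavityType(enum.Enum):
    """Cavity taxonomy: surface clefts, tunnels (one surface entry), pores
    (two surface entries), and NOTYPE for type-agnostic detections."""

    CLEFT = "CLEFT"
    TUNNEL = "TUNNEL"
    PORE = "PORE"
    NOTYPE = "NOTYPE"


@dataclass
class Cavity:
    """A cluster of pseudo-atoms identified as one cavity.

    ``volume`` (Å³) is carried when the source provides it (e.g. cleft
    datasets list cavities in decreasing volume order) and is never
    recomputed here.
    """

    id: str
    type: CavityType
    atoms: list[PseudoAtom]
    volume: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"cavity {self.id!r} has no pseudo-atoms")
        if self.volume is not None and self.volume < 0:
            raise ValueError(f"cavity {self.id!r} has negative volume")

    def __len__(self) -> int:
        return len(self.atoms)

    def centers(self) -> np.ndarray:
        """(n, 3) array of pseudo-atom centers."""
        return np.array([a.center for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        """(n,) array of pseudo-atom radii."""
        return np.array([a.radius for a in self.atoms], dtype=float)


@dataclass
class CavitySet:
    """All cavities of one protein from one source.

    Cavity order is preserved exactly as read; ground-truth sources list
    clefts in decreasing volume order and the reader never re-sorts.
    Protein ids are normalized to lowercase (sources mix 1A4U and 1a4u).
    """

    protein_id: str
    source: str
    cavities: list[Cavity] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.protein_id = self.protein_id.lower()
        ids = [c.id for c in self.cavities]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cavity ids in {self.protein_id}: {dupes}")

    def __len__(self) -> int:
        return len(self.cavities)

    def __iter__(self):
        return iter(self.cavities)

    def cavity_ids(self) -> list[str]:
        return [c.id for c in self.cavities]


@dataclass
class OverlapMatrix:
    """Per-protein grid of Jaccard values.

    Rows are method-predicted cavities, columns ground-truth cavities.
    After repetition removal each row and column holds at most one
    nonzero value (a one-to-one matching).
    """

    protein_id: str
    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    repetitions_removed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = len(self.row_ids), len(self.col_ids)
        if self.values.shape != (m, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match ids ({m}, {n})"
            )
        if self.values.size and (
            np.min(self.values) < 0 or np.max(self.values) > 1
        ):
            raise ValueError("overlap values must lie in [0, 1]")
        if self.repetitions_removed and not self._one_to_one():
            raise ValueError(
                "repetitions_removed matrix has a row/column with >1 nonzero"
            )

    def _one_to_one(self) -> bool:
        nz = self.values > 0
        return bool(
            np.all(nz.sum(axis=1) <= 1) and np.all(nz.sum(axis=0) <= 1)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClassificationCounts:
    """TP/FP/FN (and optional TN) counts for one protein or a micro-sum."""

    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))
        if self.tn is not None:
            if self.tn < 0 or int(self.tn) != self.tn:
                raise ValueError(f"tn must be a non-negative integer, got {self.tn}")
            self.tn = int(self.tn)


@dataclass(frozen=True)
class PerformanceMetrics:
    """Precision, recall and F-score; ``None`` marks an undefined value
    (zero denominator — e.g. a protein with no predicted cavities).
    Report writers render ``None`` as "NA"."""

    precision: Optional[float]
    recall: Optional[float]
    fscore: Optional[float]

    def __post_init__(self) -> None:
        for name in ("precision", "recall", "fscore"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")


def point_in_cavity(
    p: Sequence[float], cavity: Cavity, tol: float = DEFAULT_TOL
) -> bool:
    """True iff point ``p`` lies inside the sphere union of ``cavity``.

    Boundary inclusive: a point exactly one radius from a center is inside.
    ``tol`` (Å, non-negative) expands every sphere; the test is monotone in
    it.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    q = np.asarray(p, dtype=float)
    d = np.linalg.norm(cavity.centers() - q, axis=1)
    return bool(np.any(d <= cavity.radii() + tol))
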
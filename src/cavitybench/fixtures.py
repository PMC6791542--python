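"""Synthetic cavity fixtures with known (planted) classification outcomes.

The generator builds a ground-truth cavity set of well-separated sphere
blobs and a "detected" set derived from it by controlled degradations:

* **drop** — a fraction of ground-truth cavities the method misses
  (planted false negatives);
* **spurious** — extra blobs far from every true cavity (planted false
  positives);
* **split** — a surviving cavity reported as two half-clusters, a planted
  repetition: both halves overlap the same truth cavity, so one becomes a
  false positive once repetitions are removed;
* **jitter** — Gaussian positional noise on every surviving pseudo-atom,
  truncated so each displaced center stays strictly inside its own parent
  sphere.  Overlap between a surviving copy and its parent is therefore
  always nonzero, whatever the seed.

Sites sit on a lattice with pitch ``min_separation``, so distinct cavities
(and spurious blobs) can never touch.  Together the two guarantees make
the expected TP/FP/FN of both scenarios — repetitions kept and removed —
exactly computable from the construction, which is what the returned
:class:`PlantedCounts` carries.  Everything is driven by one seed;
identical seeds give identical fixtures, down to the serialized XML bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Cavity, CavitySet, CavityType, ClassificationCounts, PseudoAtom

__all__ = ["FixtureSpec", "PlantedCounts", "generate_fixture"]

_TRUTH_TYPES = [CavityType.CLEFT, CavityType.TUNNEL, CavityType.PORE]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark scenario.

    Defaults describe a mid-sized protein's worth of cavities: half a
    dozen blobs of 4–10 pseudo-atoms with 1–2 Å radii, 0.25 Å detection
    jitter, and 30 Å between cavity sites — far beyond any sphere reach,
    so only planted overlaps exist.
    """

    seed: int
    n_truth: int = 6
    atoms_per_cavity: tuple[int, int] = (4, 10)
    radius_range: tuple[float, float] = (1.0, 2.0)
    jitter_sd: float = 0.25
    drop_fraction: float = 0.0
    spurious_count: int = 0
    split_fraction: float = 0.0
    min_separation: float = 30.0

    def __post_init__(self) -> None:
        kmin, kmax = self.atoms_per_cavity
        rmin, rmax = self.radius_range
        if not (2 <= kmin <= kmax):
            raise ValueError("atoms_per_cavity must satisfy 2 <= min <= max")
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range must be positive and ordered")
        if self.n_truth < 0 or self.spurious_count < 0:
            raise ValueError("counts must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        for name in ("drop_fraction", "split_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        # blob extent: atom centers within _blob_radius of the site, so a
        # sphere reaches at most _blob_radius + rmax (+ jitter < rmax).
        if self.min_separation <= 2 * (self._blob_radius + 2 * rmax) + 3 * self.jitter_sd:
            raise ValueError(
                "infeasible separation: min_separation too small for blob "
                "extent, sphere radii and jitter"
            )

    @property
    def _blob_radius(self) -> float:
        return max(2.0 * self.radius_range[1], 2.0)


@dataclass(frozen=True)
class PlantedCounts:
    """Expected classification outcome implied by the construction, for
    both scenarios."""

    with_repetitions: ClassificationCounts
    without_repetitions: ClassificationCounts


@dataclass
class _Blob:
    site: np.ndarray
    atoms: list[PseudoAtom] = field(default_factory=list)


def _lattice_sites(n: int, pitch: float) -> np.ndarray:
    """First ``n`` points of a cubic lattice with the given pitch; any two
    distinct sites are at least ``pitch`` apart."""
    side = max(1, math.ceil(n ** (1 / 3)))
    coords = []
    for i in range(side + 1):
        for j in range(side + 1):
            for k in range(side + 1):
                coords.append((i, j, k))
                if len(coords) >= n:
                    return np.array(coords, dtype=float) * pitch
    return np.array(coords, dtype=float) * pitch


def _make_blob(rng: np.random.Generator, spec: FixtureSpec, site: np.ndarray) -> _Blob:
    kmin, kmax = spec.atoms_per_cavity
    rmin, rmax = spec.radius_range
    k = int(rng.integers(kmin, kmax + 1))
    offsets = rng.normal(0.0, spec._blob_radius / 2.0, size=(k, 3))
    norms = np.linalg.norm(offsets, axis=1)
    too_far = norms > spec._blob_radius
    offsets[too_far] *= (spec._blob_radius / norms[too_far])[:, None]
    radii = rng.uniform(rmin, rmax, size=k)
    atoms = [
        PseudoAtom(tuple(site + off), float(r)) for off, r in zip(offsets, radii)
    ]
    return _Blob(site=site, atoms=atoms)


def _jittered_copy(rng: np.random.Generator, atoms: list[PseudoAtom], sd: float) -> list[PseudoAtom]:
    """Displace each atom by truncated Gaussian noise that keeps the new
    center strictly inside the parent sphere (norm < 0.9 × radius)."""
    out = []
    for a in atoms:
        d = rng.normal(0.0, sd, size=3)
        nd = float(np.linalg.norm(d))
        cap = 0.9 * a.radius
        if nd > cap:
            d *= cap / nd
        out.append(PseudoAtom(tuple(np.asarray(a.center) + d), a.radius))
    return out


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[CavitySet, CavitySet, PlantedCounts]:
    """Build (truth, predicted, planted counts) for one scenario.

    Deterministic for a given spec.  The planted counts follow directly
    from the construction:

    * with repetitions: TP = surviving cavities + one extra per split
      (both halves hit the parent), FP = spurious blobs, FN = dropped
      cavities;
    * without repetitions: each split pair collapses to one match, moving
      one half to the false positives.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_truth + spec.spurious_count
    sites = _lattice_sites(max(n_total, 1), spec.min_separation)
    order = rng.permutation(len(sites))
    truth_sites = sites[order[: spec.n_truth]]
    spurious_sites = sites[order[spec.n_truth: n_total]]

    protein_id = f"synth{spec.seed:04d}"
    truth_cavities: list[Cavity] = []
    blobs: list[_Blob] = []
    for i, site in enumerate(truth_sites):
        blob = _make_blob(rng, spec, site)
        blobs.append(blob)
        truth_cavities.append(
            Cavity(
                id=f"truth{i + 1}",
                type=_TRUTH_TYPES[i % len(_TRUTH_TYPES)],
                atoms=blob.atoms,
            )
        )
    truth = CavitySet(protein_id=protein_id, source="synthetic-truth",
                      cavities=truth_cavities)

    n_drop = round(spec.drop_fraction * spec.n_truth)
    dropped = set(rng.choice(spec.n_truth, size=n_drop, replace=False).tolist()) \
        if n_drop else set()
    kept = [i for i in range(spec.n_truth) if i not in dropped]

    n_split = round(spec.split_fraction * len(kept))
    split = set(rng.choice(len(kept), size=n_split, replace=False).tolist()) \
        if n_split else set()

    predicted_atom_lists: list[list[PseudoAtom]] = []
    for pos, i in enumerate(kept):
        copy = _jittered_copy(rng, blobs[i].atoms, spec.jitter_sd)
        if pos in split:
            half = len(copy) // 2
            predicted_atom_lists.append(copy[:half])
            predicted_atom_lists.append(copy[half:])
        else:
            predicted_atom_lists.append(copy)
    for site in spurious_sites:
        predicted_atom_lists.append(_make_blob(rng, spec, site).atoms)

    perm = rng.permutation(len(predicted_atom_lists))
    predicted_cavities = [
        Cavity(id=f"pred{k + 1}", type=CavityType.NOTYPE,
               atoms=predicted_atom_lists[int(p)])
        for k, p in enumerate(perm)
    ]
    predicted = CavitySet(protein_id=protein_id, source="synthetic-method",
                          cavities=predicted_cavities)

    n_kept = len(kept)
    planted = PlantedCounts(
        with_repetitions=ClassificationCounts(
            tp=n_kept + n_split, fp=spec.spurious_count, fn=n_drop
        ),
        without_repetitions=ClassificationCounts(
            tp=n_kept, fp=spec.spurious_count + n_split, fn=n_drop
        ),
    )
    return truth, predicted, planted
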
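"""DBSCAN assembly of unlabeled pseudo-atom soups into cavities.

Grid-based detection methods often emit one flat list of pseudo-atoms for
a whole protein with no cavity labels.  Density-based clustering over the
sphere centers (radii ignored) recovers the cavities: a core point has at
least ``min_pts`` neighbours within ``eps`` (itself included), clusters
are connected core points plus density-reachable border points, and
isolated points are noise.  Sensible defaults when the grid spacing is
known: eps = 2 × spacing (diagonal grid neighbours connect), min_pts = 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .core import Cavity, CavityType, PseudoAtom

__all__ = ["ClusteringParams", "cluster_pseudo_atoms", "default_params_for_spacing"]


@dataclass(frozen=True)
class ClusteringParams:
    """DBSCAN parameters: neighbourhood radius ``eps`` (Å, > 0) and minimum
    neighbourhood size ``min_pts`` (self-inclusive, ≥ 1)."""

    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be at least 1")


def default_params_for_spacing(grid_spacing: float) -> ClusteringParams:
    """Defaults for grid-method soups: eps twice the spacing, min_pts 4."""
    return ClusteringParams(eps=2.0 * grid_spacing, min_pts=4)


def cluster_pseudo_atoms(
    atoms: Sequence[PseudoAtom], params: ClusteringParams
) -> tuple[list[Cavity], list[PseudoAtom]]:
    """Cluster a pseudo-atom soup into cavities plus a noise list.

    Border points reachable from several clusters go to the cluster
    discovered first in input-order scanning (the classical DBSCAN
    ambiguity, pinned for reproducibility).  Clusters are returned sorted
    by size descending, ties by smallest member index, typed NOTYPE and
    labelled "cavity1", "cavity2", …  Every input atom lands in exactly
    one cavity or in the noise list.
    """
    if not atoms:
        raise ValueError("no pseudo-atoms to cluster")
    X = np.array([a.center for a in atoms], dtype=float)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(X)

    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    noise_idx = groups.pop(-1, [])

    ordered = sorted(groups.values(), key=lambda idx: (-len(idx), idx[0]))
    cavities = [
        Cavity(
            id=f"cavity{k + 1}",
            type=CavityType.NOTYPE,
            atoms=[atoms[i] for i in idx],
        )
        for k, idx in enumerate(ordered)
    ]
    noise = [atoms[i] for i in noise_idx]
    return cavities, noise
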
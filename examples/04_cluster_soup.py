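"""Assembling an unlabeled pseudo-atom soup into cavities with DBSCAN.

Grid-based detection methods often emit one flat list of cavity grid
points for the whole protein.  Density-based clustering over the centers
recovers the individual cavities and flags stray points as noise.
"""

import numpy as np

from cavitybench import ClusteringParams, PseudoAtom, cluster_pseudo_atoms

rng = np.random.default_rng(0)
spacing = 0.8  # Å grid spacing of the hypothetical method

blob_a = rng.normal((0, 0, 0), 0.5, size=(12, 3))
blob_b = rng.normal((15, 0, 0), 0.5, size=(8, 3))
stray = np.array([[40.0, 40.0, 40.0]])
soup = [
    PseudoAtom(tuple(p), spacing / 2)  # grid methods: radius = half spacing
    for p in np.vstack([blob_a, blob_b, stray])
]

params = ClusteringParams(eps=2 * spacing, min_pts=4)
cavities, noise = cluster_pseudo_atoms(soup, params)

print(f"{len(soup)} pseudo-atoms -> {len(cavities)} cavities, {len(noise)} noise")
for cav in cavities:
    print(f"  {cav.id}: {len(cav)} atoms around {cav.centers().mean(axis=0).round(1)}")
# Two dense blobs become cavity1 (12 atoms) and cavity2 (8 atoms); the
# single far-away point has no eps-neighbourhood and is reported as noise.
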
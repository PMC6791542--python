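import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cavitybench import Cavity, CavitySet, CavityType, PseudoAtom


def make_cavity(spheres, cav_id="c", cav_type=CavityType.NOTYPE, volume=None):
    """spheres: iterable of (x, y, z, r)."""
    atoms = [PseudoAtom((x, y, z), r) for x, y, z, r in spheres]
    return Cavity(id=cav_id, type=cav_type, atoms=atoms, volume=volume)


def random_cavity(rng, cav_id="c", n_max=8, spread=5.0):
    n = int(rng.integers(1, n_max + 1))
    centers = rng.uniform(-spread, spread, size=(n, 3))
    radii = rng.uniform(0.3, 2.5, size=n)
    return Cavity(
        id=cav_id,
        type=CavityType.NOTYPE,
        atoms=[PseudoAtom(tuple(c), float(r)) for c, r in zip(centers, radii)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def hollow_cube_atoms():
    """8 corner spheres (r=1) of a cube of side 10: the interior is a void
    the convex hull encloses but no sphere covers."""
    corners = [(x, y, z) for x in (0, 10) for y in (0, 10) for z in (0, 10)]
    return [PseudoAtom(c, 1.0) for c in corners]


def empty_cavity_set(protein_id="test", source="truth"):
    return CavitySet(protein_id=protein_id, source=source, cavities=[])
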
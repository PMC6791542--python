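import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavitybench import (
    Cavity,
    CavitySet,
    CavityType,
    ClassificationCounts,
    OverlapMatrix,
    PerformanceMetrics,
    PseudoAtom,
    point_in_cavity,
)
from conftest import make_cavity
from oracles import brute_point_in_union


class TestPseudoAtom:
    @pytest.mark.parametrize("radius", [0.0, -1.0, math.nan, math.inf])
    def test_rejects_bad_radius(self, radius):
        with pytest.raises(ValueError):
            PseudoAtom((0, 0, 0), radius)

    @pytest.mark.parametrize("center", [(math.nan, 0, 0), (0, math.inf, 0), (1, 2)])
    def test_rejects_bad_center(self, center):
        with pytest.raises(ValueError):
            PseudoAtom(center, 1.0)


class TestCavity:
    def test_rejects_empty_atom_list(self):
        with pytest.raises(ValueError):
            Cavity(id="c", type=CavityType.CLEFT, atoms=[])

    def test_rejects_negative_volume(self):
        with pytest.raises(ValueError):
            make_cavity([(0, 0, 0, 1)], volume=-1.0)


class TestCavitySet:
    def test_protein_id_lowercased(self):
        s = CavitySet(protein_id="1A4U", source="truth", cavities=[])
        assert s.protein_id == "1a4u"

    def test_duplicate_cavity_ids_rejected(self):
        cavs = [make_cavity([(0, 0, 0, 1)], "x"), make_cavity([(5, 5, 5, 1)], "x")]
        with pytest.raises(ValueError):
            CavitySet(protein_id="test", source="m", cavities=cavs)

    def test_order_preserved_even_when_volumes_increase(self):
        cavs = [
            make_cavity([(0, 0, 0, 1)], "a", volume=10.0),
            make_cavity([(9, 9, 9, 1)], "b", volume=99.0),
        ]
        s = CavitySet(protein_id="test", source="truth", cavities=cavs)
        assert s.cavity_ids() == ["a", "b"]


class TestOverlapMatrixInvariants:
    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            OverlapMatrix("p", ["r1"], ["c1"], np.array([[1.5]]))

    def test_rejects_false_one_to_one_claim(self):
        with pytest.raises(ValueError):
            OverlapMatrix("p", ["r1"], ["c1", "c2"],
                          np.array([[0.5, 0.5]]), repetitions_removed=True)


class TestCountsAndMetricsTypes:
    def test_counts_reject_negative(self):
        with pytest.raises(ValueError):
            ClassificationCounts(tp=-1, fp=0, fn=0)

    def test_metrics_reject_out_of_range(self):
        with pytest.raises(ValueError):
            PerformanceMetrics(precision=1.2, recall=None, fscore=None)


class TestPointInCavity:
    @pytest.mark.parametrize(
        "point,spheres,tol,expected",
        [
            ((0, 0, 0), [(0, 0, 0, 2)], 1e-9, True),        # center of own sphere
            ((10, 0, 0), [(0, 0, 0, 1)], 1e-9, False),      # far outside
            ((1, 0, 0), [(0, 0, 0, 1)], 0.0, True),         # boundary inclusive
        ],
    )
    def test_examples(self, point, spheres, tol, expected):
        assert point_in_cavity(point, make_cavity(spheres), tol) is expected

    def test_rejects_negative_tol(self):
        with pytest.raises(ValueError):
            point_in_cavity((0, 0, 0), make_cavity([(0, 0, 0, 1)]), tol=-1e-3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_tol_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        centers = rng.uniform(-5, 5, size=(n, 3))
        radii = rng.uniform(0.2, 3.0, size=n)
        cav = make_cavity([(*c, r) for c, r in zip(centers, radii)])
        p = rng.uniform(-7, 7, size=3)
        tols = sorted(rng.uniform(0, 2, size=2))
        results = [point_in_cavity(p, cav, t) for t in tols]
        # monotone: inside at small tol stays inside at larger tol
        assert not (results[0] and not results[1])
        for t, got in zip(tols, results):
            assert got == brute_point_in_union(p, centers, radii, t)
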
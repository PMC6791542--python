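import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavitybench import (
    CavitySet,
    build_overlap_matrix,
    coverage_of_ground_truth,
    jaccard,
    write_overlap_csv,
)
from cavitybench.core import PseudoAtom, Cavity, CavityType
from conftest import make_cavity, random_cavity
from oracles import brute_jaccard


class TestJaccard:
    def test_congruent_clusters_give_one(self):
        c = make_cavity([(0, 0, 0, 2)])
        assert jaccard(c, c) == 1.0

    def test_disjoint_clusters_give_zero(self):
        a = make_cavity([(0, 0, 0, 1)])
        b = make_cavity([(10, 0, 0, 1)])
        assert jaccard(a, b) == 0.0

    def test_partial_overlap_counts_mutual_centers(self):
        # A = 2 (both centers of a inside b's union), B = 1 -> 3/4
        a = make_cavity([(0, 0, 0, 1.5), (1, 0, 0, 1.5)])
        b = make_cavity([(1, 0, 0, 1.5), (5, 0, 0, 1.0)])
        assert jaccard(a, b) == pytest.approx(0.75)

    def test_duplicate_centers_count_with_multiplicity(self):
        a = make_cavity([(0, 0, 0, 1.0), (0, 0, 0, 1.0)])
        b = make_cavity([(0, 0, 0, 1.0), (9, 0, 0, 1.0)])
        # both duplicates of a are inside b; one center of b inside a
        assert jaccard(a, b) == pytest.approx(3 / 4)

    @given(st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None)
    def test_symmetric_bounded_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_cavity(rng, "a")
        b = random_cavity(rng, "b")
        j_ab = jaccard(a, b)
        assert 0.0 <= j_ab <= 1.0
        assert j_ab == jaccard(b, a)
        expected = brute_jaccard(
            a.centers(), a.radii(), b.centers(), b.radii(), tol=1e-9
        )
        assert j_ab == expected

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_joint_translation(self, seed):
        rng = np.random.default_rng(seed)
        a = random_cavity(rng, "a")
        b = random_cavity(rng, "b")
        shift = rng.uniform(-50, 50, size=3)

        def moved(cav):
            return Cavity(
                id=cav.id, type=cav.type,
                atoms=[PseudoAtom(tuple(np.asarray(x.center) + shift), x.radius)
                       for x in cav.atoms],
            )

        assert jaccard(a, b) == pytest.approx(jaccard(moved(a), moved(b)), abs=1e-12)


class TestCoverage:
    def test_identical_and_disjoint(self):
        c = make_cavity([(0, 0, 0, 2)])
        assert coverage_of_ground_truth(c, c) == 1.0
        far = make_cavity([(30, 0, 0, 1)])
        assert coverage_of_ground_truth(c, far) == 0.0

    def test_directional_fraction(self):
        pred = make_cavity([(1, 0, 0, 1.5)])
        truth = make_cavity(
            [(1, 0, 0, 0.5), (5, 0, 0, 1), (6, 0, 0, 1), (7, 0, 0, 1)]
        )
        assert coverage_of_ground_truth(pred, truth) == pytest.approx(0.25)
        # not symmetric: truth covers pred's single center too
        assert coverage_of_ground_truth(truth, pred) == 1.0


class TestOverlapMatrix:
    def _sets(self):
        a = make_cavity([(0, 0, 0, 1.5), (1, 0, 0, 1.5)], "a")
        b = make_cavity([(20, 0, 0, 1.0)], "b")
        A = make_cavity([(1, 0, 0, 1.5), (5, 0, 0, 1.0)], "A")
        B = make_cavity([(20, 0, 0, 1.0)], "B")
        pred = CavitySet("test", "m", [a, b])
        truth = CavitySet("test", "gt", [A, B])
        return pred, truth

    def test_matrix_matches_elementwise_jaccard(self):
        pred, truth = self._sets()
        M = build_overlap_matrix(pred, truth)
        assert M.shape == (2, 2)
        assert M.row_ids == ["a", "b"] and M.col_ids == ["A", "B"]
        assert not M.repetitions_removed
        for i, c in enumerate(pred):
            for j, C in enumerate(truth):
                assert M.values[i, j] == jaccard(c, C)

    def test_empty_prediction_gives_zero_by_n(self):
        _, truth = self._sets()
        pred = CavitySet("test", "m", [])
        M = build_overlap_matrix(pred, truth)
        assert M.shape == (0, 2)

    def test_protein_mismatch_rejected(self):
        pred, truth = self._sets()
        other = CavitySet("1xyz", "gt", truth.cavities)
        with pytest.raises(ValueError):
            build_overlap_matrix(pred, other)

    def test_csv_export_layout(self):
        pred, truth = self._sets()
        M = build_overlap_matrix(pred, truth)
        buf = io.StringIO()
        write_overlap_csv(M, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == ",A,B"
        assert lines[1].startswith("a,") and lines[2].startswith("b,")
        cell = lines[1].split(",")[1]
        assert cell == f"{M.values[0, 0]:.4f}"
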
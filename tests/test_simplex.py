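"""Aitchison-geometry primitives: closure, SBP/ilr, means, reallocation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wakecomp.simplex import (
    Composition,
    CompositionError,
    DegenerateCompositionError,
    InfeasibleReallocationError,
    SequentialBinaryPartition,
    check_zeros,
    close,
    compositional_mean,
    ilr_forward,
    ilr_inverse,
    logratio_diff,
    make_default_sbp,
    make_pivot_sbp,
    reallocate,
)

from conftest import random_simplex_points

positive_parts = st.tuples(
    st.floats(0.01, 1000), st.floats(0.01, 1000), st.floats(0.01, 1000)
)


def ilr_oracle(p):
    """Direct evaluation of the two pivot log-ratio formulas."""
    sb, lpa, mvpa = p
    return (
        np.sqrt(2 / 3) * np.log(sb / np.sqrt(lpa * mvpa)),
        np.sqrt(1 / 2) * np.log(lpa / mvpa),
    )


class TestClose:
    @pytest.mark.parametrize(
        "parts,kappa,expected",
        [
            ((451.24, 200.90, 71.81), 100, (62.33, 27.75, 9.92)),
            ((1, 1, 1), 3, (1, 1, 1)),
            ((10, 20, 70), 1, (0.1, 0.2, 0.7)),
        ],
    )
    def test_examples(self, parts, kappa, expected):
        c = close(parts, kappa)
        assert np.allclose(np.round(c.parts, 2), expected)
        assert c.parts.sum() == pytest.approx(kappa, rel=1e-9)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateCompositionError):
            close((0, 0, 0), 1)

    def test_negative_part_rejected(self):
        with pytest.raises(CompositionError):
            close((1, -1, 2), 1)

    @given(positive_parts)
    def test_idempotence(self, parts):
        once = close(parts, 724.0)
        twice = close(once.parts, 724.0)
        assert np.allclose(once.parts, twice.parts, rtol=1e-12)

    def test_composition_invariants(self):
        with pytest.raises(CompositionError):
            Composition(np.array([1.0, 2.0]), ("a", "a"), 3.0)
        with pytest.raises(CompositionError):
            Composition(np.array([1.0, 2.0, 3.0]), ("a", "b", "c"), 10.0)


class TestCheckZeros:
    def test_all_positive_empty(self):
        assert len(check_zeros(np.ones((3, 3)))) == 0

    def test_single_zero_located(self):
        t = np.ones((3, 3))
        t[1, 2] = 0
        rep = check_zeros(t)
        assert rep.entries == ((1, "MVPA"),)

    def test_two_zeros_in_one_row(self):
        t = np.ones((2, 3))
        t[0, 0] = t[0, 1] = 0
        assert len(check_zeros(t)) == 2

    def test_negative_rejected(self):
        with pytest.raises(CompositionError):
            check_zeros(np.array([[1.0, -1.0, 1.0]]))


class TestSbp:
    def test_default_contrast_reproduces_pivot_formula(self):
        b = make_default_sbp()
        row1 = np.sqrt(2 / 3) * np.array([1, -0.5, -0.5])
        row2 = np.sqrt(1 / 2) * np.array([0, 1, -1])
        assert np.allclose(b.contrast_matrix, [row1, row2])

    def test_orthonormality(self):
        for pivot in ("SB", "LPA", "MVPA"):
            b = make_pivot_sbp(("SB", "LPA", "MVPA"), pivot)
            assert np.allclose(
                b.contrast_matrix @ b.contrast_matrix.T, np.eye(2), atol=1e-12
            )

    def test_permuted_labels_same_pattern(self):
        b = make_default_sbp(("MVPA", "SB", "LPA"))
        assert np.allclose(b.sign_matrix, [[1, -1, -1], [0, 1, -1]])

    def test_wrong_dimension_rejected(self):
        with pytest.raises(CompositionError):
            make_default_sbp(("a", "b"))

    def test_invalid_partition_rejected(self):
        # row 2 reuses the part isolated by row 1
        with pytest.raises(CompositionError):
            SequentialBinaryPartition(np.array([[1, -1, -1], [1, 0, -1]]))
        with pytest.raises(CompositionError):
            SequentialBinaryPartition(np.array([[1, 1, 1], [0, 1, -1]]))


class TestIlr:
    def test_equal_parts_map_to_origin(self):
        z = ilr_forward(close((1, 1, 1), 1))
        assert np.allclose(z, 0, atol=1e-12)

    def test_table_mean_composition(self):
        p = (0.6233, 0.2775, 0.0992)
        z = ilr_forward(close(p, 1))
        assert np.allclose(z, ilr_oracle(p), atol=1e-12)
        assert np.allclose(np.round(z, 4), (1.0807, 0.7274))

    @given(positive_parts)
    def test_scale_invariance(self, parts):
        z1 = ilr_forward(close(parts, 1.0))
        z724 = ilr_forward(close(parts, 724.0))
        assert np.allclose(z1, z724, atol=1e-9)

    def test_zero_part_error_names_part(self):
        with pytest.raises(CompositionError, match="LPA"):
            ilr_forward(np.array([0.5, 0.0, 0.5]))

    def test_monotone_in_pivot_share(self):
        # growing SB at a fixed LPA:MVPA ratio must raise ilr1
        shares = np.linspace(0.1, 0.9, 9)
        z1 = [
            ilr_forward(close((s, (1 - s) * 0.7, (1 - s) * 0.3), 1))[0]
            for s in shares
        ]
        assert np.all(np.diff(z1) > 0)


class TestIlrInverse:
    def test_origin_maps_to_barycenter(self):
        c = ilr_inverse((0.0, 0.0), kappa=1.0)
        assert np.allclose(c.parts, 1 / 3)

    def test_round_trip_random_points(self, rng):
        pts = random_simplex_points(1000, rng)
        z = ilr_forward(pts)
        back = ilr_inverse(z, kappa=1.0)
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_inverse_of_table_mean(self):
        z = ilr_oracle((0.6233, 0.2775, 0.0992))
        c = ilr_inverse(z, kappa=1.0)
        assert np.allclose(np.round(c.parts, 4), (0.6233, 0.2775, 0.0992))

    def test_nonfinite_rejected(self):
        with pytest.raises(CompositionError):
            ilr_inverse((np.inf, 0.0))


class TestCompositionalMean:
    def test_identical_rows(self):
        c = close((62.33, 27.75, 9.92), 1)
        m = compositional_mean([c, c, c])
        assert np.allclose(m.parts, c.parts, rtol=1e-12)

    def test_two_row_geometric_mean(self):
        rows = [close((0.5, 0.3, 0.2), 1), close((0.2, 0.3, 0.5), 1)]
        gm = np.array([np.sqrt(0.10), 0.3, np.sqrt(0.10)])
        expected = gm / gm.sum()
        assert np.allclose(compositional_mean(rows).parts, expected, rtol=1e-12)

    def test_row_permutation_invariance(self, rng):
        pts = random_simplex_points(50, rng)
        m1 = compositional_mean(pts)
        m2 = compositional_mean(pts[::-1].copy())
        assert np.allclose(m1.parts, m2.parts, rtol=1e-12)

    def test_equals_ilr_space_mean(self, rng):
        # cross-oracle: geometric-mean route == inverse of mean ilr
        pts = random_simplex_points(200, rng)
        m_geo = compositional_mean(pts)
        m_ilr = ilr_inverse(ilr_forward(pts).mean(axis=0), kappa=1.0)
        assert np.max(np.abs(m_geo.parts - m_ilr.parts)) < 1e-9

    def test_empty_rejected(self):
        with pytest.raises(CompositionError):
            compositional_mean([])


class TestLogratioDiff:
    def test_identical_means_zero(self):
        c = close((62, 28, 10), 1)
        assert np.allclose(logratio_diff(c, c), 0)

    def test_perturbation_example(self):
        overall = close((0.5, 0.3, 0.2), 1)
        group = close(overall.parts * np.array([2.0, 1.0, 1.0]), 1)
        d = logratio_diff(group, overall)
        ln2 = np.log(2.0)
        assert np.allclose(d, (2 * ln2 / 3, -ln2 / 3, -ln2 / 3), atol=1e-12)

    def test_antisymmetry(self, rng):
        a = close(random_simplex_points(1, rng)[0], 1)
        b = close(random_simplex_points(2, rng)[1], 1)
        assert np.allclose(logratio_diff(a, b), -logratio_diff(b, a), atol=1e-12)

    def test_label_mismatch_rejected(self):
        a = close((1, 2, 3), 1, labels=("a", "b", "c"))
        b = close((1, 2, 3), 1, labels=("x", "y", "z"))
        with pytest.raises(CompositionError):
            logratio_diff(a, b)


class TestReallocate:
    def test_five_minutes_sb_to_lpa(self):
        c = Composition(np.array([451.24, 200.90, 71.81]), kappa=723.95)
        out = reallocate(c, "SB", "LPA", 5.0)
        assert np.allclose(out.parts, (446.24, 205.90, 71.81))
        assert out.kappa == c.kappa

    def test_zero_delta_identity(self):
        c = close((400, 250, 74), 724)
        out = reallocate(c, "SB", "MVPA", 0.0)
        assert np.allclose(out.parts, c.parts)

    def test_exhausting_a_part_is_infeasible(self):
        c = Composition(np.array([10.0, 5.0, 5.0]), kappa=20.0)
        with pytest.raises(InfeasibleReallocationError):
            reallocate(c, "MVPA", "SB", 5.0)

    def test_same_part_rejected(self):
        c = close((1, 1, 1), 3)
        with pytest.raises(CompositionError):
            reallocate(c, "SB", "SB", 0.5)

    @given(positive_parts, st.floats(0, 0.99))
    def test_conserves_total(self, parts, frac):
        c = close(parts, 724.0)
        delta = frac * c.part("SB") * 0.999
        out = reallocate(c, "SB", "MVPA", delta)
        assert out.parts.sum() == pytest.approx(724.0, abs=1e-9)
        assert out.part("LPA") == c.part("LPA")


def test_matches_scikit_bio_ilr(rng):
    """Independent oracle: scikit-bio's ilr with the same contrast basis."""
    from skbio.stats.composition import ilr as skbio_ilr

    pts = random_simplex_points(100, rng)
    basis = make_default_sbp()
    ours = ilr_forward(pts, basis)
    theirs = skbio_ilr(pts, basis=basis.contrast_matrix)
    assert np.allclose(ours, theirs, atol=1e-10)
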
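"""clr/ilr transforms, the clinical SBP basis, distances and biplots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from skbio.stats.composition import clr as skbio_clr

from cgmcoda.composition import close
from cgmcoda.coordinates import (
    DEFAULT_BASIS,
    DEFAULT_SBP,
    DomainError,
    aitchison_distance,
    clr_biplot_coords,
    clr_inverse,
    clr_transform,
    compositional_center,
    ilr_inverse,
    ilr_transform,
    sbp_basis,
    validate_sbp,
)

from conftest import WORKED_CLR, WORKED_ILR, WORKED_MINUTES

positive_comp = st.lists(st.floats(1e-3, 1e4), min_size=5, max_size=5).map(np.asarray)


class TestSBP:
    def test_default_sbp_is_valid(self):
        validate_sbp(DEFAULT_SBP)

    def test_basis_rows_orthonormal_and_zero_sum(self):
        psi = sbp_basis(DEFAULT_SBP)
        np.testing.assert_allclose(psi @ psi.T, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(psi.sum(axis=1), 0.0, atol=1e-12)

    def test_first_balance_coefficient(self):
        # 2 plus-parts vs 3 minus-parts: sqrt(r*s/(r+s)) = sqrt(6/5)
        row = DEFAULT_SBP[0]
        coeff = np.sqrt(2 * 3 / 5)
        x = WORKED_MINUTES
        gm_plus = np.exp(np.log(x[row > 0]).mean())
        gm_minus = np.exp(np.log(x[row < 0]).mean())
        assert coeff == pytest.approx(np.sqrt(6 / 5))
        assert ilr_transform(x)[0] == pytest.approx(coeff * np.log(gm_plus / gm_minus))

    @pytest.mark.parametrize(
        "bad",
        [
            [[1, 1, -1, -1, -1], [1, -1, 0, 0, 0], [0, 0, -1, 1, 1]],  # too few rows
            [[1, 1, 1, 1, 1], [1, -1, 0, 0, 0], [0, 0, -1, 1, 1], [0, 0, 0, -1, 1]],
            [[1, 1, -1, -1, -1], [0, 0, -1, 1, 1], [1, -1, 0, 1, 0], [0, 0, 0, -1, 1]],
        ],
    )
    def test_invalid_sbp_rejected(self, bad):
        with pytest.raises(ValueError):
            sbp_basis(np.asarray(bad))


class TestClr:
    def test_worked_example(self):
        np.testing.assert_allclose(clr_transform(WORKED_MINUTES), WORKED_CLR,
                                   atol=5e-5)

    def test_uniform_maps_to_zero(self):
        np.testing.assert_allclose(clr_transform(np.full(5, 288.0)), np.zeros(5),
                                   atol=1e-14)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(5), size=20)
        np.testing.assert_allclose(clr_transform(X), skbio_clr(X), atol=1e-12)

    def test_round_trip(self):
        x = close(WORKED_MINUTES, 1440.0)
        back = clr_inverse(clr_transform(x), C=1440.0)
        np.testing.assert_allclose(np.asarray(back), np.asarray(x), rtol=1e-12)

    def test_zero_part_named_in_error(self):
        with pytest.raises(DomainError, match="t_lt54"):
            clr_transform(np.array([0.0, 1, 1, 1, 1]))


class TestIlr:
    def test_worked_example(self):
        np.testing.assert_allclose(ilr_transform(WORKED_MINUTES), WORKED_ILR,
                                   atol=5e-5)

    def test_equal_hypo_times_zero_second_balance(self):
        x = np.array([17.0, 17.0, 1000.0, 300.0, 106.0])
        assert ilr_transform(x)[1] == pytest.approx(0.0, abs=1e-12)

    def test_ilr_is_clr_projected_on_basis(self):
        rng = np.random.default_rng(1)
        X = rng.dirichlet(np.ones(5), size=10)
        np.testing.assert_allclose(
            ilr_transform(X), clr_transform(X) @ DEFAULT_BASIS.T, atol=1e-13
        )

    def test_round_trip(self):
        y = ilr_transform(WORKED_MINUTES)
        back = ilr_inverse(y, C=1440.0)
        np.testing.assert_allclose(np.asarray(back), WORKED_MINUTES, rtol=1e-10)


class TestAitchisonDistance:
    def test_self_distance_zero(self):
        assert aitchison_distance(WORKED_MINUTES, WORKED_MINUTES) == 0.0

    def test_distance_from_uniform_composition(self):
        d = aitchison_distance(np.ones(5), WORKED_MINUTES)
        assert d == pytest.approx(1.1764, abs=5e-5)

    @given(x=positive_comp, y=positive_comp)
    @settings(max_examples=100, derandomize=True)
    def test_isometry_with_ilr_coordinates(self, x, y):
        d_clr = aitchison_distance(x, y)
        d_ilr = np.linalg.norm(ilr_transform(x) - ilr_transform(y))
        assert abs(d_clr - d_ilr) < 1e-10

    @given(x=positive_comp, y=positive_comp, z=positive_comp)
    @settings(max_examples=50, derandomize=True)
    def test_metric_axioms(self, x, y, z):
        dxy = aitchison_distance(x, y)
        assert dxy == pytest.approx(aitchison_distance(y, x), abs=1e-10)
        assert dxy <= aitchison_distance(x, z) + aitchison_distance(z, y) + 1e-10

    def test_permutation_equivariance(self):
        perm = np.array([2, 0, 4, 1, 3])
        x = WORKED_MINUTES
        y = np.array([100.0, 340.0, 700.0, 250.0, 50.0])
        assert aitchison_distance(x[perm], y[perm]) == pytest.approx(
            aitchison_distance(x, y), abs=1e-12
        )


class TestCenter:
    def test_identical_rows_return_that_row(self):
        X = np.tile(close(WORKED_MINUTES, 1.0), (4, 1))
        np.testing.assert_allclose(
            np.asarray(compositional_center(X, 1.0)), X[0], rtol=1e-12
        )

    def test_hand_computed_geometric_means(self):
        X = np.array([[1, 1, 2, 4, 8], [4, 4, 2, 1, 2]], dtype=float)
        center = compositional_center(X, 1.0)
        np.testing.assert_allclose(
            np.asarray(center), [1 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 3], rtol=1e-12
        )

    def test_center_commutes_with_closure(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(1, 100, size=(6, 5))
        Xc = np.asarray([np.asarray(close(r, 1.0)) for r in X])
        a = np.asarray(compositional_center(X, 1440.0))
        b = np.asarray(compositional_center(Xc, 1440.0))
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compositional_center(np.empty((0, 5)))


class TestBiplot:
    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(5)
        X = rng.dirichlet(np.ones(5), size=30)
        _, _, explained = clr_biplot_coords(X)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1 + 1e-9

    def test_one_dimensional_data_detected_as_degenerate(self):
        base = clr_transform(WORKED_MINUTES)
        X = np.asarray([np.asarray(clr_inverse(t * base)) for t in (0.5, 1.0, 1.5, 2.0)])
        with pytest.raises(ValueError, match="rank"):
            clr_biplot_coords(X)

    def test_full_rank_scores_reproduce_aitchison_distances(self):
        rng = np.random.default_rng(6)
        X = rng.dirichlet(np.ones(5), size=4)
        scores, _, _ = clr_biplot_coords(X)
        d_scores = pdist(scores)
        d_aitch = pdist(clr_transform(X))
        np.testing.assert_allclose(d_scores, d_aitch, rtol=1e-10)
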
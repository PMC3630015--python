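"""Similarity contracts: coordinates are plain Pearson correlations with
the reference variates, M factorizes as coords_X @ coords_Y', |M| <= 1,
and regression-mode PLS at full rank recovers the Pearson cross-correlation
matrix exactly."""

import numpy as np
import pytest

from paircorr import (
    PairedDataset,
    coords_cca,
    coords_pls,
    fit_cca,
    fit_pls,
    fit_rcca,
    fit_spls,
    similarity_from_fit,
    similarity_matrix,
)
from paircorr.similarity import VariableCoordinates, pls_similarity_closed_form

from conftest import random_dataset


def naive_corr(mat, refs):
    out = np.empty((mat.shape[1], refs.shape[1]))
    for j in range(mat.shape[1]):
        for l in range(refs.shape[1]):
            out[j, l] = np.corrcoef(mat[:, j], refs[:, l])[0, 1]
    return out


class TestCoordinates:
    def test_cca_coords_match_naive_correlation_loop(self, rng):
        data = random_dataset(rng, n=40, p=4, q=3)
        fit = fit_cca(data, 2)
        cx, cy = coords_cca(fit, data)
        z = fit.u[:, :2] + fit.v[:, :2]
        assert np.abs(cx.values - naive_corr(data.x, z)).max() < 1e-12
        assert np.abs(cy.values - naive_corr(data.y, z)).max() < 1e-12

    def test_cca_coords_invariant_to_reference_rescaling(self, rng):
        """Correlations ignore positive rescaling of the equiangular axis,
        so coordinates computed from 10x-scaled variates are identical."""
        data = random_dataset(rng, n=30, p=4, q=3)
        fit = fit_cca(data, 2)
        cx, _ = coords_cca(fit, data)
        z = 10.0 * (fit.u[:, :2] + fit.v[:, :2])
        assert np.abs(cx.values - naive_corr(data.x, z)).max() < 1e-12

    def test_perfectly_correlated_pair_sits_at_unit_radius(self, rng):
        x = rng.standard_normal((25, 1))
        data = PairedDataset(x, 2.0 * x.copy()).standardize()
        fit = fit_cca(data, 1)
        cx, cy = coords_cca(fit, data)
        assert abs(cx.values[0, 0]) == pytest.approx(1.0, abs=1e-10)
        assert abs(cy.values[0, 0]) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("mode", ["reg", "can"])
    def test_pls_coords_match_closed_form(self, small_data, mode):
        """Empirical correlations equal u_l*phi (and sigma_l*psi) from the
        stored fit coefficients."""
        fit = fit_pls(small_data, 3, mode)
        cx, cy = coords_pls(fit, small_data)
        expected_x = fit.u_sd * fit.phi
        assert np.abs(cx.values - expected_x).max() < 1e-8
        sd = fit.u_sd if mode == "reg" else fit.v_sd
        assert np.abs(cy.values - sd * fit.psi).max() < 1e-8

    def test_bessel_bound_on_rows(self, sim30):
        fit = fit_pls(sim30, 3, "can")
        cx, cy = coords_pls(fit, sim30)
        for c in (cx, cy):
            assert np.sqrt((c.values**2).sum(axis=1)).max() <= 1 + 1e-8

    def test_sparse_fit_restricts_coordinates_to_selected(self, small_data):
        fit = fit_spls(small_data, 2, "can", keep_x=3, keep_y=2)
        cx, cy = coords_pls(fit, small_data)
        assert set(cx.ids) == set(fit.selected_x())
        assert set(cy.ids) == set(fit.selected_y())
        assert len(cx.ids) <= 6 and len(cy.ids) <= 4

    def test_method_family_dispatch_enforced(self, small_data):
        pls = fit_pls(small_data, 2, "can")
        with pytest.raises(ValueError):
            coords_cca(pls, small_data)
        cca = fit_cca(small_data, 2)
        with pytest.raises(ValueError):
            coords_pls(cca, small_data)

    def test_excess_dimensions_rejected(self, small_data):
        fit = fit_pls(small_data, 2, "can")
        with pytest.raises(ValueError):
            coords_pls(fit, small_data, d=3)


class TestSimilarityMatrix:
    def test_factorization_is_exact(self, small_data):
        fit = fit_pls(small_data, 3, "can")
        cx, cy = coords_pls(fit, small_data)
        m = similarity_matrix(cx, cy)
        assert np.array_equal(m.values, cx.values @ cy.values.T)

    def test_entries_bounded_by_one(self, sim30):
        for fit in (fit_pls(sim30, 3, "can"), fit_rcca(sim30, 3, 0.889, 0.889)):
            m = similarity_from_fit(fit, sim30, 3)
            assert np.abs(m.values).max() <= 1 + 1e-8

    def test_pls_reg_full_rank_recovers_pearson(self, rng):
        """At d = rank(X) the regression-mode decomposition is exhaustive,
        so M equals the Pearson cross-correlation matrix entrywise."""
        data = random_dataset(rng, n=12, p=6, q=4)
        fit = fit_pls(data, 6, "reg")
        m = similarity_from_fit(fit, data)
        pearson = np.corrcoef(data.x, data.y, rowvar=False)[:6, 6:]
        assert np.abs(m.values - pearson).max() < 1e-6

    def test_frobenius_norm_nondecreasing_in_d(self, sim30):
        fit = fit_pls(sim30, 4, "can")
        norms = [
            np.linalg.norm(similarity_from_fit(fit, sim30, d).values)
            for d in range(1, 5)
        ]
        assert (np.diff(norms) >= -1e-12).all()

    def test_orthogonal_coordinate_rows_give_zero_entry(self):
        cx = VariableCoordinates(np.array([[1.0, 0.0]]), ["x1"], "X", "U")
        cy = VariableCoordinates(np.array([[0.0, 1.0]]), ["y1"], "Y", "U")
        assert similarity_matrix(cx, cy).values[0, 0] == 0.0

    def test_dimension_mismatch_rejected(self):
        cx = VariableCoordinates(np.array([[0.5, 0.1]]), ["x1"], "X", "U")
        cy = VariableCoordinates(np.array([[0.5]]), ["y1"], "Y", "U")
        with pytest.raises(ValueError):
            similarity_matrix(cx, cy)

    def test_approximates_pearson_on_relevant_blocks(self, sim500):
        """d=3 canonical-mode similarity tracks the Pearson cross-
        correlation over the relevant variable pairs (mean abs error
        < 0.1 at n=500)."""
        fit = fit_pls(sim500, 3, "can")
        m = similarity_from_fit(fit, sim500, 3)
        pearson = sim500.x.T @ sim500.y / (sim500.n - 1)
        diff = np.abs(m.values - pearson)[:23, :17]
        assert diff.mean() < 0.1

    def test_canonical_closed_form_matches_correlation_route(self, sim30):
        fit = fit_pls(sim30, 3, "can")
        m = similarity_from_fit(fit, sim30, 3)
        closed = pls_similarity_closed_form(fit, 3)
        assert np.abs(m.values - closed).max() < 1e-8
        printed = pls_similarity_closed_form(fit, 3, printed_form=True)
        assert np.abs(m.values - printed).max() > 1e-3  # variant differs

    def test_paper_design_block_separation(self, sim30):
        """A-block pairs are strongly negative, noise-only pairs weak."""
        m = similarity_from_fit(fit_pls(sim30, 3, "can"), sim30, 3).to_frame()
        a_block = m.loc[[f"XA{i}" for i in range(1, 11)],
                        [f"YA{i}" for i in range(1, 11)]]
        assert (a_block.values < -0.5).all()
        noise = m.loc[[i for i in m.index if i.startswith("noise_")],
                      [c for c in m.columns if c.startswith("noise_")]]
        assert (np.abs(noise.values) < 0.5).all()

    def test_a_block_opposite_on_dimension_one(self, sim30):
        """X_A and Y_A sit diametrically opposite on dimension 1: the
        product of their dimension-1 coordinates is negative for every
        A-pair."""
        cx, cy = coords_pls(fit_pls(sim30, 3, "can"), sim30)
        xa = cx.values[:10, 0]
        ya = cy.values[:10, 0]
        assert (np.outer(xa, ya) < 0).all()
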
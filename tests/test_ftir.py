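"""Savitzky-Golay filtering, region cutting and EMSC."""

import numpy as np
import pandas as pd
import pytest

from coldchem.ftir import (
    DEFAULT_REMOVE_REGIONS,
    NonUniformGridError,
    Spectrum,
    SpectrumSet,
    cut_regions,
    emsc_correct,
    emsc_fit,
    pipeline_pca,
    pipeline_ratio,
    savgol,
    select_region,
)
from coldchem.synthetic import default_grid


def spectrum_from(w, y):
    return Spectrum(np.asarray(w, float), np.asarray(y, float))


def sg_second_derivative_oracle(w, y, window=11, poly_order=2):
    """Independent per-window local polynomial fit (interior points)."""
    half = window // 2
    out = np.full_like(y, np.nan)
    for i in range(half, len(w) - half):
        sl = slice(i - half, i + half + 1)
        coeffs = np.polyfit(w[sl] - w[i], y[sl], poly_order)
        out[i] = 2.0 * coeffs[poly_order - 2]
    return out


class TestSavgol:
    def test_constant_has_zero_second_derivative(self, grid):
        s = savgol(spectrum_from(grid, np.full_like(grid, 3.7)),
                   deriv_order=2)
        assert np.allclose(s.values, 0.0, atol=1e-10)

    def test_quadratic_second_derivative_is_exact(self, grid):
        y = 0.5 * (grid - 2000.0) ** 2
        s = savgol(spectrum_from(grid, y), deriv_order=2)
        assert np.allclose(s.values, 1.0, atol=1e-8)

    def test_cubic_matches_window_polyfit_oracle(self, grid):
        w = grid[:200]
        y = ((w - 3800.0) / 100.0) ** 3
        s = savgol(spectrum_from(w, y), deriv_order=2)
        expected = sg_second_derivative_oracle(w, y)
        interior = ~np.isnan(expected)
        assert np.allclose(s.values[interior], expected[interior],
                           atol=1e-8)

    def test_random_input_matches_oracle(self, grid, rng):
        w = grid[:150]
        y = rng.normal(size=w.size)
        s = savgol(spectrum_from(w, y), deriv_order=2)
        expected = sg_second_derivative_oracle(w, y)
        interior = ~np.isnan(expected)
        assert np.allclose(s.values[interior], expected[interior],
                           atol=1e-8)

    def test_smoothing_preserves_polynomials_up_to_order(self, grid):
        y = 2.0 + 0.001 * grid
        s = savgol(spectrum_from(grid, y), deriv_order=0)
        assert np.allclose(s.values, y, atol=1e-8)

    def test_nonuniform_grid_instructs_resampling(self):
        w = np.array([4000.0, 3990.0, 3985.0, 3975.0, 3960.0, 3950.0,
                      3940.0, 3930.0, 3920.0, 3910.0, 3900.0, 3890.0])
        with pytest.raises(NonUniformGridError, match="resample"):
            savgol(spectrum_from(w, np.zeros_like(w)))

    def test_invalid_window_rejected(self, grid):
        with pytest.raises(ValueError):
            savgol(spectrum_from(grid, np.zeros_like(grid)), window=10)


class TestCutRegions:
    def test_default_regions_match_direct_count(self, grid):
        # no acquisition grid point falls exactly on a region boundary,
        # so the retained count is the direct count in the two windows
        s = cut_regions(spectrum_from(grid, np.zeros_like(grid)))
        expected = np.sum((grid > 2800) & (grid < 3100)) + \
            np.sum((grid > 900) & (grid < 1800))
        assert s.wavenumbers.size == expected
        assert not np.any((s.wavenumbers > 1800) & (s.wavenumbers < 2800))

    def test_empty_removal_list_is_identity(self, grid):
        y = np.sin(grid / 100.0)
        s = cut_regions(spectrum_from(grid, y), remove=[])
        assert np.array_equal(s.wavenumbers, grid)
        assert np.array_equal(s.values, y)

    def test_shared_boundary_point_goes_with_the_removed_region(self):
        w = np.array([3104.0, 3102.0, 3100.0, 3098.0, 3096.0])
        s = cut_regions(spectrum_from(w, np.ones_like(w)),
                        remove=[(4000.0, 3100.0)])
        assert 3100.0 not in s.wavenumbers
        assert 3098.0 in s.wavenumbers

    def test_idempotence(self, grid):
        s0 = spectrum_from(grid, np.cos(grid / 50.0))
        once = cut_regions(s0)
        twice = cut_regions(once)
        assert np.array_equal(once.wavenumbers, twice.wavenumbers)
        assert np.array_equal(once.values, twice.values)

    def test_removing_everything_raises(self, grid):
        with pytest.raises(ValueError):
            cut_regions(spectrum_from(grid, np.zeros_like(grid)),
                        remove=[(5000.0, 0.0)])


def make_set(grid, matrix):
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(matrix.shape[0])],
        "replicate": [0] * matrix.shape[0],
    })
    return SpectrumSet(grid, matrix, meta)


class TestEMSC:
    @pytest.fixture()
    def reference(self, grid):
        return np.exp(-0.5 * ((grid - 1650.0) / 40.0) ** 2) + \
            0.5 * np.exp(-0.5 * ((grid - 1080.0) / 30.0) ** 2)

    def test_reference_fits_itself(self, grid, reference):
        sset = make_set(grid, reference[None, :])
        model = emsc_fit(sset, reference=reference)
        a = model.baseline_coefficients[0]
        assert model.gains[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(a, 0.0, atol=1e-10)

    def test_affine_construction_recovers_coefficients(self, grid,
                                                       reference):
        sset = make_set(grid, (2.0 * reference + 5.0)[None, :])
        model = emsc_fit(sset, reference=reference)
        assert model.gains[0] == pytest.approx(2.0, abs=1e-10)
        # constant offset lands on the degree-0 Legendre coefficient
        assert model.baseline_coefficients[0][0] == \
            pytest.approx(5.0, abs=1e-9)
        corrected = emsc_correct(sset, model)
        assert np.allclose(corrected.matrix[0], reference, atol=1e-9)

    def test_coefficients_match_normal_equations_oracle(self, grid,
                                                        reference, rng):
        matrix = rng.normal(size=(5, grid.size))
        sset = make_set(grid, matrix)
        model = emsc_fit(sset, reference=reference)
        design = model.design_matrix()
        oracle = np.linalg.solve(design.T @ design,
                                 design.T @ matrix.T).T
        assert np.allclose(model.coefficients, oracle, atol=1e-8)

    def test_correction_is_idempotent(self, grid, reference, rng):
        matrix = (rng.uniform(0.5, 2.0, size=(4, 1)) * reference
                  + rng.normal(scale=0.05, size=(4, grid.size)))
        sset = make_set(grid, matrix)
        model = emsc_fit(sset, reference=reference)
        once = emsc_correct(sset, model)
        model2 = emsc_fit(once, reference=reference)
        twice = emsc_correct(once, model2)
        assert np.allclose(once.matrix, twice.matrix, atol=1e-10)

    def test_mean_reference_mean_of_corrected_is_reference(self, grid,
                                                           reference,
                                                           rng):
        gains = rng.uniform(0.5, 2.0, size=(6, 1))
        matrix = gains * reference + rng.normal(0, 0.3, size=(6, 1))
        sset = make_set(grid, matrix)
        model = emsc_fit(sset, reference="mean")
        corrected = emsc_correct(sset, model)
        # the spectra are exact affine images of the mean, so the mean of
        # the corrected set reproduces the reference (zero mean residual)
        assert np.allclose(corrected.matrix.mean(axis=0),
                           model.reference, atol=1e-8)

    def test_singular_design_raises(self, grid):
        # reference collinear with the quadratic baseline columns
        x = np.linspace(-1, 1, grid.size)
        ref = 1.0 + 2.0 * x + 3.0 * x ** 2
        sset = make_set(grid, np.vstack([ref, 2 * ref]))
        with pytest.raises(np.linalg.LinAlgError):
            emsc_fit(sset, reference=ref)

    def test_uncorrectable_spectra_are_flagged_not_dropped(self, grid,
                                                           reference):
        # one spectrum orthogonal to the reference -> b ~ 0
        matrix = np.vstack([reference, np.zeros_like(reference)])
        sset = make_set(grid, matrix)
        model = emsc_fit(sset, reference=reference, b_tol=1e-6)
        assert list(model.uncorrectable) == [False, True]
        corrected = emsc_correct(sset, model)
        assert list(corrected.metadata["emsc_uncorrectable"]) == \
            [False, True]
        dropped = emsc_correct(sset, model, drop_uncorrectable=True)
        assert dropped.matrix.shape[0] == 1


class TestPipelines:
    @pytest.fixture()
    def sset(self, grid, rng):
        base = np.exp(-0.5 * ((grid - 1656.0) / 10.0) ** 2)
        matrix = rng.uniform(0.8, 1.2, size=(4, 1)) * base \
            + rng.normal(0, 0.001, size=(4, grid.size))
        return make_set(grid, matrix)

    def test_pca_path_excludes_cut_regions(self, sset):
        out = pipeline_pca(sset)
        w = out.wavenumbers
        assert not np.any((w > 1800) & (w < 2800))
        assert not np.any((w > 3100) | (w < 900))

    def test_ratio_path_span(self, sset):
        out = pipeline_ratio(sset)
        assert out.wavenumbers.max() <= 1900.0
        assert out.wavenumbers.min() >= 900.0

    def test_pipelines_are_deterministic(self, sset):
        a = pipeline_pca(sset)
        b = pipeline_pca(sset)
        assert np.array_equal(a.matrix, b.matrix)
        c = pipeline_ratio(sset)
        d = pipeline_ratio(sset)
        assert np.array_equal(c.matrix, d.matrix)


def test_ascending_grid_is_normalized_to_descending():
    w = np.array([400.0, 500.0, 600.0])
    s = Spectrum(w, np.array([1.0, 2.0, 3.0]))
    assert np.array_equal(s.wavenumbers, [600.0, 500.0, 400.0])
    assert np.array_equal(s.values, [3.0, 2.0, 1.0])


def test_select_region_outside_span_raises(grid):
    with pytest.raises(ValueError):
        select_region(spectrum_from(grid, np.zeros_like(grid)),
                      region=(120.0, 30.0))
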
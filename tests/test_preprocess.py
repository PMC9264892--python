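"""Preprocessing chain: EMSC against an independent least-squares oracle,
crop/normalize/bin arithmetic, chain order and model inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serodisc import (CohortConfig, PreprocessConfig, SpectralDataset,
                      bin_spectra, crop_region, emsc_correct, make_axis,
                      run_preprocess, simulate_cohort, vector_normalize)
from serodisc.errors import DegenerateDataError, RangeError


def emsc_oracle(x, ref, axis, order):
    """Independent EMSC solution via plain-monomial normal equations."""
    t = 2 * (axis - axis.min()) / (axis.max() - axis.min()) - 1
    D = np.column_stack([ref] + [t**k for k in range(order + 1)])
    coef = np.linalg.solve(D.T @ D, D.T @ x)
    b, poly_coef = coef[0], coef[1:]
    baseline = D[:, 1:] @ poly_coef
    return (x - baseline) / b


def _wrap(rows, axis):
    rows = np.atleast_2d(rows)
    meta = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(rows))],
        "class": ["cancer"] * len(rows),
        "bio_rep": [1] * len(rows),
        "tech_rep": [1] * len(rows),
    })
    return SpectralDataset(rows, axis, meta)


class TestEmsc:
    def test_self_correction_identity(self):
        axis = make_axis(1800, 1000, 10)
        ref = np.exp(-0.5 * ((axis - 1500) / 60) ** 2)
        ds = _wrap(ref.copy(), axis)
        out, diag = emsc_correct(ds, ref, order=2, return_diagnostics=True)
        np.testing.assert_allclose(out.matrix[0], ref, atol=1e-10)
        assert diag["b"][0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(diag["c"][0], 0.0, atol=1e-10)

    def test_exact_linear_model_recovered(self):
        axis = make_axis(1800, 1000, 10)
        ref = 0.2 + np.exp(-0.5 * ((axis - 1400) / 50) ** 2)
        ds = _wrap(2.0 * ref + 5.0, axis)
        out, diag = emsc_correct(ds, ref, order=0, return_diagnostics=True)
        np.testing.assert_allclose(out.matrix[0], ref, atol=1e-9)
        assert diag["b"][0] == pytest.approx(2.0, abs=1e-9)
        assert diag["a"][0] == pytest.approx(5.0, abs=1e-8)

    @pytest.mark.parametrize("order", [0, 1, 2, 3, 4])
    def test_matches_normal_equations_oracle(self, order):
        rng = np.random.default_rng(55 + order)
        axis = np.sort(rng.uniform(1000, 1800, size=50))[::-1]
        ref = rng.uniform(0.1, 1.0, size=50)
        x = rng.normal(size=50)
        out = emsc_correct(_wrap(x.copy(), axis), ref, order=order)
        np.testing.assert_allclose(out.matrix[0],
                                   emsc_oracle(x, ref, axis, order),
                                   atol=1e-8)

    def test_zero_reference_rejected(self):
        axis = make_axis(1800, 1000, 10)
        with pytest.raises(DegenerateDataError):
            emsc_correct(_wrap(np.ones(axis.size), axis),
                         np.zeros(axis.size), order=2)

    def test_vanishing_scale_names_row(self):
        axis = make_axis(1800, 1000, 10)
        ref = np.exp(-0.5 * ((axis - 1500) / 60) ** 2)
        orthogonal = np.ones(axis.size)  # spanned by the baseline, b ~ 0
        ds = _wrap(np.vstack([ref, orthogonal]), axis)
        with pytest.raises(DegenerateDataError, match="row 1"):
            emsc_correct(ds, ref, order=2)


class TestCrop:
    def test_fingerprint_region_point_count(self, full_axis):
        ds = _wrap(np.random.default_rng(1).normal(size=(2, full_axis.size)),
                   full_axis)
        out = crop_region(ds, 1800, 1000)
        assert out.n_points == 401
        assert out.axis.max() == 1800 and out.axis.min() == 1000

    def test_identity_crop(self, tiny_dataset):
        out = crop_region(tiny_dataset, tiny_dataset.axis.max(),
                          tiny_dataset.axis.min())
        np.testing.assert_array_equal(out.matrix, tiny_dataset.matrix)

    def test_disjoint_crop_rejected(self, tiny_dataset):
        with pytest.raises(RangeError):
            crop_region(tiny_dataset, 100, 50)


class TestVectorNormalize:
    def test_rows_have_zero_mean_unit_norm(self, tiny_dataset):
        out = vector_normalize(tiny_dataset)
        np.testing.assert_allclose(out.matrix.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(out.matrix, axis=1), 1.0,
                                   atol=1e-12)

    def test_two_point_row_hand_value(self):
        axis = np.array([1600.0, 1000.0])
        out = vector_normalize(_wrap(np.array([1.0, -1.0]), axis))
        np.testing.assert_allclose(out.matrix[0],
                                   [np.sqrt(2) / 2, -np.sqrt(2) / 2])

    @given(c=st.floats(0.1, 50), d=st.floats(-20, 20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, c, d):
        axis = np.linspace(1800.0, 1000.0, 16)
        rng = np.random.default_rng(8)
        x = rng.normal(size=16)
        a = vector_normalize(_wrap(x, axis)).matrix
        b = vector_normalize(_wrap(c * x + d, axis)).matrix
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_constant_row_rejected(self):
        axis = np.linspace(1800.0, 1000.0, 8)
        with pytest.raises(DegenerateDataError):
            vector_normalize(_wrap(np.full(8, 3.3), axis))


class TestBinning:
    def test_401_points_factor_8_gives_50_bins(self, full_axis):
        ds = _wrap(np.random.default_rng(2).normal(size=(3, full_axis.size)),
                   full_axis)
        out = bin_spectra(crop_region(ds, 1800, 1000), 8)
        assert out.n_points == 50  # floor(401 / 8), one point dropped

    def test_factor_one_is_identity(self, tiny_dataset):
        out = bin_spectra(tiny_dataset, 1)
        np.testing.assert_array_equal(out.matrix, tiny_dataset.matrix)

    @given(value=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_constant_spectrum_preserved(self, value):
        axis = np.linspace(1800.0, 1000.0, 24)
        out = bin_spectra(_wrap(np.full(24, value), axis), 4)
        np.testing.assert_allclose(out.matrix, value, atol=1e-12)

    def test_factor_exceeding_points_rejected(self, tiny_dataset):
        with pytest.raises(RangeError):
            bin_spectra(tiny_dataset, 100)


class TestChain:
    def test_default_chain_dimensionality(self, small_cohort, prep_cfg):
        out = run_preprocess(small_cohort, prep_cfg)
        assert out.n_points == 50
        assert out.n_spectra == small_cohort.n_spectra

    def test_chain_inverts_generator_distortions(self, full_axis):
        """Zero biological/technical noise: after EMSC the scatter and
        baseline are removed, so all spectra of one class coincide."""
        cfg = CohortConfig(n_cases=4, n_controls=4, effect_size=2.0,
                           marker_sd=0.0, patient_sd=0.0, bio_sd=0.0,
                           tech_sd=0.0, scatter_sd=0.3, baseline_sd=0.1,
                           baseline_order=2, seed=21)
        ds = simulate_cohort(cfg, full_axis)
        corrected = emsc_correct(ds, ds.matrix.mean(axis=0), order=2)
        for cls in (0, 1):
            block = corrected.matrix[ds.y == cls]
            assert np.abs(block - block[0]).max() < 1e-6

    def test_supplied_reference_matches_staged_chain(self, small_cohort):
        """run_preprocess with an explicit (pooled-style) reference equals
        the stage-by-stage chain applied manually."""
        ref = small_cohort.matrix.mean(axis=0)
        out = run_preprocess(small_cohort,
                             PreprocessConfig(emsc_reference=ref))
        manual = bin_spectra(
            vector_normalize(
                crop_region(emsc_correct(small_cohort, ref, 2), 1800, 1000)),
            8)
        np.testing.assert_allclose(out.matrix, manual.matrix, atol=1e-10)
        np.testing.assert_allclose(out.axis, manual.axis)

    def test_stage_order_is_enforced(self, small_cohort):
        """Cropping before EMSC changes the polynomial fit; the chain must
        therefore run EMSC first."""
        ref = small_cohort.matrix.mean(axis=0)
        chain = crop_region(emsc_correct(small_cohort, ref, 2), 1800, 1000)
        ref_cropped = crop_region(small_cohort, 1800, 1000)
        swapped = emsc_correct(ref_cropped,
                               ref_cropped.matrix.mean(axis=0), 2)
        assert not np.allclose(chain.matrix, swapped.matrix, atol=1e-6)

    def test_row_permutation_equivariance(self, small_cohort, prep_cfg):
        out = run_preprocess(small_cohort, prep_cfg)
        perm = np.random.default_rng(5).permutation(small_cohort.n_spectra)
        out_perm = run_preprocess(small_cohort.take_rows(perm), prep_cfg)
        np.testing.assert_allclose(out_perm.matrix, out.matrix[perm],
                                   atol=1e-10)
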
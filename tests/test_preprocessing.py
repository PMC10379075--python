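"""Preprocessing transforms: exact examples, invariances, scatter removal."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from freshnir import GeneratorConfig, generate_dataset
from freshnir.core import SpectraSet
from freshnir.preprocessing import (
    PreprocessSpec,
    apply_minmax_norm,
    apply_msc,
    apply_savgol,
    apply_snv,
    fit_preprocessor,
)
from freshnir.synthetic_data import noiseless


def make_set(X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wl = 700.0 + np.arange(X.shape[1])
    ids = np.array([f"s{i}" for i in range(X.shape[0])], dtype=object)
    return SpectraSet(X, wl, ids)


class TestMSC:
    def test_exact_affine_distortion_recovered(self):
        ref = np.array([1.0, 2.0, 3.0])
        out = apply_msc(make_set([[3.0, 5.0, 7.0]]), reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-12)

    def test_reference_itself_unchanged(self):
        ref = np.array([0.3, 0.9, 0.1, 0.5])
        out = apply_msc(make_set([ref]), reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-12)

    def test_refit_oracle_a_zero_b_one(self, rng):
        """MSC output re-regressed on the reference gives a=0, b=1."""
        X = rng.normal(size=(5, 20))
        ref = X.mean(axis=0)
        out = apply_msc(make_set(X), reference=ref).absorbance
        refc = ref - ref.mean()
        for row in out:
            b = (row - row.mean()) @ refc / (refc @ refc)
            a = row.mean() - b * ref.mean()
            assert abs(a) < 1e-10
            assert abs(b - 1.0) < 1e-10

    def test_constant_spectrum_passed_through_with_warning(self):
        ref = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="constant spectra"):
            out = apply_msc(make_set([[5.0, 5.0, 5.0]]), reference=ref)
        np.testing.assert_array_equal(out.absorbance[0], [5.0, 5.0, 5.0])


class TestSNV:
    def test_three_point_example(self):
        out = apply_snv(make_set([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-12)

    @given(arrays(np.float64, (3, 12),
                  elements=st.floats(-10, 10, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_affine_invariant(self, X):
        X = X + np.linspace(0, 2, 12)  # avoid constant rows
        if np.any(X.std(axis=1, ddof=1) < 1e-9):
            return
        once = apply_snv(make_set(X)).absorbance
        twice = apply_snv(make_set(once)).absorbance
        np.testing.assert_allclose(twice, once, atol=1e-9)
        scaled = apply_snv(make_set(5.0 * X + 2.0)).absorbance
        np.testing.assert_allclose(scaled, once, atol=1e-9)

    def test_zero_variance_spectrum_names_sample(self):
        with pytest.raises(ValueError, match="s0"):
            apply_snv(make_set([[1.0, 1.0, 1.0]]))


class TestMinMax:
    def test_example_and_bounds(self, rng):
        out = apply_minmax_norm(make_set([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.absorbance[0], [0.0, 0.5, 1.0])
        X = rng.normal(size=(6, 30))
        out = apply_minmax_norm(make_set(X)).absorbance
        np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=1), 1.0, atol=1e-12)

    def test_negation_reverses_ordering(self):
        x = np.array([[0.1, 0.7, 0.4, 1.0]])
        up = apply_minmax_norm(make_set(x)).absorbance[0]
        down = apply_minmax_norm(make_set(-x)).absorbance[0]
        np.testing.assert_allclose(up + down, 1.0, atol=1e-12)


class TestSavgol:
    def test_second_derivative_of_quadratic_is_two(self):
        wl = np.arange(30, dtype=float)
        spectra = SpectraSet((wl**2)[None, :], wl + 700.0,
                             np.array(["s0"], dtype=object))
        # unit grid: pass window/polyorder so that lambda^2 -> constant 2
        out = apply_savgol(spectra, window=7, polyorder=2, deriv=2)
        np.testing.assert_allclose(out.absorbance[0], 2.0, atol=1e-8)

    def test_smoothing_preserves_constant_and_deriv_of_line(self):
        n = 25
        wl = 700.0 + 1.0 * np.arange(n)
        const = SpectraSet(np.full((1, n), 3.7), wl, np.array(["a"], dtype=object))
        out = apply_savgol(const, 11, 2, deriv=0)
        np.testing.assert_allclose(out.absorbance, 3.7, atol=1e-10)
        line = SpectraSet((3.0 * wl + 1.0)[None, :], wl, np.array(["b"], dtype=object))
        d1 = apply_savgol(line, 11, 2, deriv=1)
        np.testing.assert_allclose(d1.absorbance, 3.0, atol=1e-8)

    def test_invalid_window_rejected(self):
        s = make_set(np.zeros((1, 20)))
        with pytest.raises(ValueError, match="odd"):
            apply_savgol(s, window=10, polyorder=2)
        with pytest.raises(ValueError, match="polyorder"):
            apply_savgol(s, window=5, polyorder=5)


def test_all_transforms_shape_preserving(small_dataset):
    spectra, _, _ = small_dataset
    for method in ("msc", "snv", "norm", "sg", "sg1", "sg2"):
        fitted = fit_preprocessor(PreprocessSpec(method=method), spectra)
        out = fitted.transform(spectra)
        assert out.absorbance.shape == spectra.absorbance.shape
        np.testing.assert_array_equal(out.wavelengths_nm, spectra.wavelengths_nm)


def test_msc_and_snv_remove_scatter_exactly_in_noiseless_limit():
    """Multiplicative+additive scatter is invisible after MSC or SNV."""
    base = GeneratorConfig(seed=9, n_channels=161, wavelength_step_nm=12.0)
    clean_cfg = noiseless(base)
    scattered_cfg = replace(clean_cfg, scatter_mult_sd=0.08, scatter_add_sd=0.04)
    clean, _, _ = generate_dataset(clean_cfg)
    scattered, _, _ = generate_dataset(scattered_cfg)
    ref = clean.absorbance.mean(axis=0)
    msc_scattered = apply_msc(scattered, reference=ref).absorbance
    msc_clean = apply_msc(clean, reference=ref).absorbance
    np.testing.assert_allclose(msc_scattered, msc_clean, atol=1e-8)
    snv_scattered = apply_snv(scattered).absorbance
    snv_clean = apply_snv(clean).absorbance
    np.testing.assert_allclose(snv_scattered, snv_clean, atol=1e-8)


def test_fitted_transform_uses_only_training_statistics(small_dataset):
    """Transforming a prediction set twice gives identical output."""
    spectra, _, _ = small_dataset
    train = spectra.select_samples(spectra.sample_ids[:40])
    test = spectra.select_samples(spectra.sample_ids[40:])
    fitted = fit_preprocessor(PreprocessSpec(method="msc"), train)
    once = fitted.transform(test).absorbance
    twice = fitted.transform(test).absorbance
    np.testing.assert_array_equal(once, twice)
    # the stored reference comes from the training set, not the test set
    np.testing.assert_array_equal(fitted.msc_references[0],
                                  train.absorbance.mean(axis=0))
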
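"""Pretreatments: MSC, mean centering, SG smoothing/derivative, chains."""

import hashlib

import numpy as np
import pytest

from teaspec.preprocessing import (
    Pretreatment,
    apply_center,
    apply_msc,
    fit_center,
    fit_msc,
    make_pretreatment,
    sg_derivative,
    sg_smooth,
)


@pytest.fixture
def spectra(rng):
    base = np.sin(np.linspace(0, 4, 60))
    return np.array([a * base + b + rng.normal(0, 0.01, 60)
                     for a, b in [(1.0, 0.0), (1.4, 0.2), (0.7, -0.1), (1.1, 0.05)]])


class TestMSC:
    def test_reference_row_unchanged(self, spectra):
        ref = fit_msc(spectra)
        out = apply_msc(ref[None, :], ref)
        assert np.allclose(out[0], ref, atol=1e-10)

    def test_affine_distortion_removed(self, spectra):
        ref = fit_msc(spectra)
        distorted = 2.0 * ref + 3.0
        assert np.allclose(apply_msc(distorted[None, :], ref)[0], ref, atol=1e-10)

    def test_post_msc_regression_is_identity(self, spectra):
        ref = fit_msc(spectra)
        corrected = apply_msc(spectra, ref)
        refc = ref - ref.mean()
        for row in corrected:
            a = (row - row.mean()) @ refc / (refc @ refc)
            b = row.mean() - a * ref.mean()
            assert a == pytest.approx(1.0, abs=1e-10)
            assert b == pytest.approx(0.0, abs=1e-10)

    def test_idempotence(self, spectra):
        ref = fit_msc(spectra)
        once = apply_msc(spectra, ref)
        twice = apply_msc(once, ref)
        assert np.allclose(once, twice, atol=1e-8)

    def test_single_row_fit_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_msc(np.ones((1, 10)))

    def test_constant_row_rejected(self, spectra):
        ref = fit_msc(spectra)
        with pytest.raises(ValueError, match="constant"):
            apply_msc(np.full((1, 60), 0.5), ref)


class TestCentering:
    def test_calibration_columns_centered(self, spectra):
        means = fit_center(spectra)
        out = apply_center(spectra, means)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_row_equal_to_means_maps_to_zero(self, spectra):
        means = fit_center(spectra)
        assert np.allclose(apply_center(means[None, :], means), 0.0)

    def test_single_calibration_row_maps_itself_to_zero(self):
        row = np.arange(10.0)[None, :]
        assert np.allclose(apply_center(row, fit_center(row)), 0.0)

    def test_band_count_mismatch_rejected(self, spectra):
        with pytest.raises(ValueError):
            apply_center(spectra[:, :30], fit_center(spectra))


class TestSavitzkyGolay:
    def test_polynomial_reproduction(self):
        x = np.linspace(-1, 1, 50)
        poly = 3 * x**2 - x + 0.5
        out = sg_smooth(poly[None, :], window=11, polyorder=2)
        assert np.allclose(out[0], poly, atol=1e-10)

    def test_full_order_window_is_identity(self, rng):
        X = rng.uniform(size=(2, 40))
        assert np.allclose(sg_smooth(X, window=7, polyorder=6), X, atol=1e-8)

    def test_matches_windowed_least_squares_refit(self, rng):
        """Interior channels equal a brute-force per-window polynomial fit."""
        x = rng.uniform(size=80)
        window, order, half = 11, 2, 5
        out = sg_smooth(x[None, :], window=window, polyorder=order)[0]
        for i in range(half, 80 - half):
            t = np.arange(-half, half + 1, dtype=float)
            coef = np.polyfit(t, x[i - half : i + half + 1], order)
            assert out[i] == pytest.approx(np.polyval(coef, 0.0), abs=1e-6)

    def test_commutes_with_constant_shift(self, rng):
        X = rng.uniform(size=(3, 40))
        assert np.allclose(sg_smooth(X + 5.0), sg_smooth(X) + 5.0, atol=1e-10)

    @pytest.mark.parametrize("window,order", [(10, 2), (5, 5), (101, 2)])
    def test_invalid_windows_rejected(self, window, order):
        with pytest.raises(ValueError):
            sg_smooth(np.zeros((1, 40)), window=window, polyorder=order)


class TestSGDerivative:
    def test_linear_spectrum_gives_constant_slope(self):
        wl = np.linspace(400, 1000, 61)
        spacing = wl[1] - wl[0]
        spec = 0.002 * wl
        d = sg_derivative(spec[None, :], spacing_nm=spacing)[0]
        assert np.allclose(d[3:-3], 0.002, atol=1e-10)

    def test_constant_annihilated(self):
        d = sg_derivative(np.full((1, 30), 0.7))
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_quadratic_analytic_derivative(self):
        wl = np.linspace(0.0, 10.0, 101)
        spacing = wl[1] - wl[0]
        a = 0.3
        d = sg_derivative((a * wl**2)[None, :], spacing_nm=spacing)[0]
        assert np.allclose(d[3:-3], 2 * a * wl[3:-3], atol=1e-8)

    def test_zero_order_rejected(self):
        with pytest.raises(ValueError):
            sg_derivative(np.zeros((1, 30)), polyorder=0)


class TestPretreatmentChains:
    def test_centering_uses_train_means_on_test(self, spectra, rng):
        spec = make_pretreatment("CT").fit(spectra)
        test = rng.uniform(size=(2, 60))
        out = spec.apply(test)
        assert np.allclose(out, test - spectra.mean(axis=0))

    def test_shape_preserved(self, rng):
        X = rng.uniform(size=(5, 943))
        spec = make_pretreatment("D1").fit(X)
        assert spec.apply(X).shape == (5, 943)

    def test_chain_equals_sequential_application(self, spectra):
        chain = Pretreatment(["SG", "CT"]).fit(spectra)
        smoothed = sg_smooth(spectra)
        expect = apply_center(smoothed, fit_center(smoothed))
        assert np.allclose(chain.apply(spectra), expect, atol=1e-12)

    def test_no_leakage_params_frozen_after_fit(self, spectra, rng):
        spec = Pretreatment(["MSC", "CT"]).fit(spectra)
        before = hashlib.sha256(
            b"".join(np.ascontiguousarray(v).tobytes() for v in spec.fitted_.values())
        ).hexdigest()
        spec.apply(rng.uniform(size=(10, 60)))
        after = hashlib.sha256(
            b"".join(np.ascontiguousarray(v).tobytes() for v in spec.fitted_.values())
        ).hexdigest()
        assert before == after

    def test_apply_before_fit_rejected(self, spectra):
        with pytest.raises(RuntimeError, match="before fit"):
            make_pretreatment("CT").apply(spectra)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown pretreatment"):
            make_pretreatment("SNV")
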
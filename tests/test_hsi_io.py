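"""Cube calibration, band trimming, mean-spectrum extraction, ENVI codec."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teaspec import (
    SpectralCube,
    calibrate_reflectance,
    extract_mean_spectrum,
    read_envi_cube,
    trim_bands,
    write_envi_cube,
)
from teaspec.synthetic import simulate_cube

WL6 = np.linspace(400, 1000, 6)


def _cube(data, wl=None, kind="raw"):
    return SpectralCube(np.asarray(data, float), wl if wl is not None else WL6, kind=kind)


class TestCalibrateReflectance:
    white = np.full(6, 0.9)
    dark = np.full(6, 0.1)

    def test_raw_equal_white_gives_unit_reflectance(self):
        raw = _cube(np.broadcast_to(self.white, (3, 4, 6)).copy())
        out = calibrate_reflectance(raw, self.white, self.dark)
        assert np.allclose(out.data, 1.0)
        assert out.kind == "reflectance"

    def test_raw_equal_dark_gives_zero(self):
        raw = _cube(np.broadcast_to(self.dark, (3, 4, 6)).copy())
        assert np.allclose(calibrate_reflectance(raw, self.white, self.dark).data, 0.0)

    def test_midpoint_gives_half(self):
        raw = _cube(np.full((2, 2, 6), 0.5))
        assert np.allclose(calibrate_reflectance(raw, self.white, self.dark).data, 0.5)

    def test_degenerate_band_error_names_the_band(self):
        white = self.white.copy()
        white[3] = self.dark[3]
        raw = _cube(np.full((2, 2, 6), 0.5))
        with pytest.raises(ValueError, match="band index 3"):
            calibrate_reflectance(raw, white, self.dark)

    @given(st.floats(-5, 5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_invariance_per_band_offset(self, c):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.2, 0.8, (2, 3, 6))
        base = calibrate_reflectance(_cube(raw), self.white, self.dark)
        shifted = calibrate_reflectance(_cube(raw + c), self.white + c, self.dark + c)
        assert np.allclose(base.data, shifted.data, atol=1e-9)

    def test_out_of_range_reflectance_warns_not_clips(self):
        raw = _cube(np.full((1, 1, 6), 1.5))
        with pytest.warns(UserWarning, match="outside"):
            out = calibrate_reflectance(raw, self.white, self.dark)
        assert out.data.max() > 1.0


class TestExtractMeanSpectrum:
    def test_uniform_cube(self):
        cube = _cube(np.full((3, 3, 6), 0.4), kind="raw")
        ms = extract_mean_spectrum(cube, np.ones((3, 3), bool))
        assert np.allclose(ms.values, 0.4)
        assert ms.pixel_count == 9

    def test_two_pixel_average(self):
        data = np.zeros((1, 2, 6))
        data[0, 0], data[0, 1] = 0.2, 0.6
        ms = extract_mean_spectrum(_cube(data), np.ones((1, 2), bool))
        assert np.allclose(ms.values, 0.4)

    def test_permutation_invariance_over_pixels(self, rng):
        data = rng.uniform(0, 1, (4, 5, 6))
        cube = _cube(data)
        mask = rng.uniform(size=(4, 5)) > 0.3
        ms = extract_mean_spectrum(cube, mask)
        perm = rng.permutation(20)
        shuffled = _cube(data.reshape(20, 6)[perm].reshape(4, 5, 6))
        ms2 = extract_mean_spectrum(shuffled, mask.reshape(20)[perm].reshape(4, 5))
        assert np.allclose(ms.values, ms2.values)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mpty mask"):
            extract_mean_spectrum(_cube(np.zeros((2, 2, 6))), np.zeros((2, 2), bool))

    def test_mean_within_clt_bound_of_generating_spectrum(self):
        wl = np.linspace(400, 1000, 20)
        spectrum = np.full(20, 0.5)
        sigma = 0.01
        sim = simulate_cube(spectrum, wl, 40, 40, pixel_noise_sd=sigma,
                            background_fraction=0.0, seed=2)
        ms = extract_mean_spectrum(sim.reflectance, sim.foreground_mask)
        assert np.all(np.abs(ms.values - spectrum) < 4 * sigma / np.sqrt(ms.pixel_count))


class TestTrimBands:
    def test_default_trim_951_to_943(self):
        X = np.zeros((2, 951))
        wl = np.linspace(400, 1000, 951)
        Xt, wlt = trim_bands((X, wl))
        assert Xt.shape == (2, 943) and wlt.shape == (943,)
        assert wlt[0] == wl[4] and wlt[-1] == wl[-5]

    def test_zero_trim_is_identity(self):
        X, wl = np.arange(20.0).reshape(2, 10), np.linspace(1, 10, 10)
        Xt, wlt = trim_bands((X, wl), 0, 0)
        assert np.array_equal(Xt, X) and np.array_equal(wlt, wl)

    def test_explicit_indices(self):
        X, wl = np.arange(10.0)[None, :], np.arange(10.0)
        Xt, wlt = trim_bands((X, wl), 3, 3)
        assert np.array_equal(wlt, [3, 4, 5, 6])

    def test_composition(self, rng):
        X, wl = rng.uniform(size=(3, 30)), np.arange(30.0)
        once = trim_bands(trim_bands((X, wl), 2, 3), 4, 1)
        twice = trim_bands((X, wl), 6, 4)
        assert np.array_equal(once[0], twice[0]) and np.array_equal(once[1], twice[1])

    def test_over_trim_rejected(self):
        with pytest.raises(ValueError):
            trim_bands((np.zeros((1, 8)), np.arange(8.0)), 4, 4)

    def test_cube_trim_preserves_kind(self):
        cube = _cube(np.zeros((2, 2, 6)), kind="raw")
        out = trim_bands(cube, 1, 1)
        assert out.kind == "raw" and out.n_bands == 4


class TestEnviRoundTrip:
    def test_cube_round_trip_bit_identical(self, rng, tmp_path):
        data = rng.uniform(0, 1, (4, 5, 6)).astype(np.float32).astype(np.float64)
        cube = _cube(data, kind="raw")
        write_envi_cube(cube, tmp_path / "c")
        back = read_envi_cube(tmp_path / "c")
        assert np.array_equal(back.data, cube.data)
        assert np.allclose(back.wavelengths_nm, cube.wavelengths_nm)
        assert back.kind == "raw"

    def test_frames_round_trip_with_kind(self, tmp_path):
        frame = SpectralCube(np.full((1, 1, 6), 0.9), WL6, kind="white")
        write_envi_cube(frame, tmp_path / "w")
        assert read_envi_cube(tmp_path / "w").kind == "white"

    def test_wavelength_count_mismatch_rejected(self, tmp_path):
        cube = _cube(np.zeros((2, 2, 6)), kind="raw")
        write_envi_cube(cube, tmp_path / "c")
        hdr = (tmp_path / "c.hdr").read_text().replace("bands = 6", "bands = 5")
        (tmp_path / "c.hdr").write_text(hdr)
        with pytest.raises(ValueError, match="wavelength list"):
            read_envi_cube(tmp_path / "c")

    def test_missing_wavelength_field_rejected(self, tmp_path):
        cube = _cube(np.zeros((2, 2, 6)), kind="raw")
        write_envi_cube(cube, tmp_path / "c")
        hdr = "\n".join(l for l in (tmp_path / "c.hdr").read_text().splitlines()
                        if not l.startswith("wavelength"))
        (tmp_path / "c.hdr").write_text(hdr)
        with pytest.raises(ValueError, match="wavelength"):
            read_envi_cube(tmp_path / "c")

    def test_bil_interleave_read(self, rng, tmp_path):
        data = rng.uniform(0, 1, (3, 4, 5)).astype("<f4")
        wl = np.linspace(400, 1000, 5)
        bil = np.ascontiguousarray(np.moveaxis(data, 2, 1))  # (lines, bands, samples)
        bil.tofile(tmp_path / "c.img")
        wl_str = ", ".join(f"{v:.6f}" for v in wl)
        (tmp_path / "c.hdr").write_text(
            "ENVI\nsamples = 4\nlines = 3\nbands = 5\ndata type = 4\n"
            f"interleave = bil\nbyte order = 0\ncube kind = raw\nwavelength = {{ {wl_str} }}\n"
        )
        back = read_envi_cube(tmp_path / "c")
        assert np.allclose(back.data, data.astype(np.float64))

    def test_unsupported_interleave_rejected(self, tmp_path):
        cube = _cube(np.zeros((2, 2, 6)), kind="raw")
        write_envi_cube(cube, tmp_path / "c")
        hdr = (tmp_path / "c.hdr").read_text().replace("interleave = bsq", "interleave = bip")
        (tmp_path / "c.hdr").write_text(hdr)
        with pytest.raises(ValueError, match="interleave"):
            read_envi_cube(tmp_path / "c")
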
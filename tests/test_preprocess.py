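import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from lymphir import (BaselineSpec, SgParams, SpectralCube, WavenumberAxis,
                     absorbance_from_single_beam, baseline_correct, bin_pixels,
                     second_derivative, truncate, vector_normalize)
from lymphir.errors import RangeError


@pytest.fixture
def axis726():
    return WavenumberAxis.from_range(900.0, 3800.0, 4.0)


class TestAbsorbance:
    def test_equal_beams_give_zero(self, axis8):
        b = np.full(8, 2.0)
        s = np.broadcast_to(b, (3, 3, 8))
        cube = absorbance_from_single_beam(s, b, axis8)
        np.testing.assert_allclose(cube.absorbance, 0.0, atol=1e-15)

    def test_one_decade_attenuation_is_unit_absorbance(self, axis8):
        b = np.full(8, 5.0)
        cube = absorbance_from_single_beam(
            np.broadcast_to(0.1 * b, (2, 2, 8)), b, axis8)
        np.testing.assert_allclose(cube.absorbance, 1.0, rtol=1e-12)

    def test_matches_elementwise_log_oracle(self, rng, axis8):
        s = rng.uniform(0.1, 2.0, size=(4, 4, 8))
        b = rng.uniform(0.5, 2.0, size=8)
        cube = absorbance_from_single_beam(s, b, axis8)
        oracle = np.empty_like(s)
        for r in range(4):
            for c in range(4):
                for k in range(8):
                    oracle[r, c, k] = -np.log10(s[r, c, k] / b[k])
        np.testing.assert_allclose(cube.absorbance, oracle, atol=1e-12)

    def test_nonpositive_sample_clamped_not_raised(self, axis8, caplog):
        b = np.full(8, 1.0)
        s = np.full((1, 1, 8), 0.5)
        s[0, 0, 3] = -1.0
        cube = absorbance_from_single_beam(s, b, axis8)
        assert np.isfinite(cube.absorbance).all()
        assert cube.absorbance[0, 0, 3] > cube.absorbance[0, 0, 0]


class TestTruncate:
    def test_default_range_endpoints(self, rng):
        ax = WavenumberAxis.from_range(800.0, 4000.0, 4.0)
        cube = SpectralCube(rng.normal(size=(2, 2, len(ax))), ax)
        out = truncate(cube, 900.0, 3800.0)
        assert out.axis.lo == 900.0 and out.axis.hi == 3800.0

    def test_full_range_is_identity(self, random_cube):
        out = truncate(random_cube, random_cube.axis.lo, random_cube.axis.hi)
        np.testing.assert_array_equal(out.absorbance, random_cube.absorbance)

    def test_matches_filter_comprehension_oracle(self, rng):
        ax = WavenumberAxis.from_range(950.0, 1450.0, 7.5)
        cube = SpectralCube(rng.normal(size=(2, 3, len(ax))), ax)
        lo, hi = 1001.0, 1333.0
        out = truncate(cube, lo, hi)
        kept = [v for v in ax.values if lo <= v <= hi]
        np.testing.assert_allclose(out.axis.values, kept)
        idx = [i for i, v in enumerate(ax.values) if lo <= v <= hi]
        np.testing.assert_array_equal(out.absorbance,
                                      cube.absorbance[:, :, idx])

    def test_nested_truncation_collapses(self, random_cube):
        ax = random_cube.axis
        once = truncate(truncate(random_cube, ax.lo, ax.hi),
                        ax.values[2], ax.values[5])
        direct = truncate(random_cube, ax.values[2], ax.values[5])
        np.testing.assert_array_equal(once.absorbance, direct.absorbance)

    def test_empty_range_raises(self, random_cube):
        with pytest.raises(RangeError):
            truncate(random_cube, 5000.0, 6000.0)


class TestBaseline:
    def test_straight_line_maps_to_zero(self, axis726):
        nu = axis726.values
        spectrum = 0.003 * nu + 1.7
        out = baseline_correct(spectrum, axis726,
                               BaselineSpec((1000.0, 3500.0)))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_triangular_peak_on_offset_recovered(self, axis726):
        nu = axis726.values
        peak = np.clip(1.0 - np.abs(nu - 1654.0) / 100.0, 0.0, None)
        out = baseline_correct(peak + 0.42, axis726,
                               BaselineSpec((1000.0, 3500.0)))
        np.testing.assert_allclose(out, peak, atol=1e-12)

    def test_interpolation_oracle_at_3075(self, rng, axis726):
        spectrum = rng.normal(0.5, 0.1, size=len(axis726))
        spec = BaselineSpec((2500.0, 3700.0))
        out = baseline_correct(spectrum, axis726, spec)
        i = axis726.index_of(3075.0)
        il, ir = axis726.index_of(2500.0), axis726.index_of(3700.0)
        nu = axis726.values
        line = (spectrum[il] + (spectrum[ir] - spectrum[il])
                * (nu[i] - nu[il]) / (nu[ir] - nu[il]))
        assert out[i] == pytest.approx(spectrum[i] - line, abs=1e-12)
        assert out[il] == pytest.approx(0.0, abs=1e-12)
        assert out[ir] == pytest.approx(0.0, abs=1e-12)


class TestSecondDerivative:
    def test_constant_maps_to_zero(self, axis726):
        cube = SpectralCube(np.full((2, 2, len(axis726)), 0.7), axis726)
        out = second_derivative(cube)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_quadratic_gives_2a_everywhere(self, axis726):
        a, b, c = 3e-7, -1e-3, 0.6
        nu = axis726.values
        spec = a * nu ** 2 + b * nu + c
        cube = SpectralCube(np.broadcast_to(spec, (2, 2, len(nu))).copy(),
                            axis726)
        out = second_derivative(cube, SgParams(13, 2, 2))
        np.testing.assert_allclose(out.absorbance, 2 * a, atol=1e-10)
        # edges trimmed: 6 bands lost each side
        assert out.n_bands == len(nu) - 12

    def test_sine_matches_convolution_oracle(self, axis726):
        omega = 0.05
        nu = axis726.values
        spec = np.sin(omega * nu)
        cube = SpectralCube(spec.reshape(1, 1, -1).copy(), axis726)
        params = SgParams(13, 2, 2)
        out = second_derivative(cube, params).absorbance[0, 0]
        # explicit SG coefficient convolution, derivative scaling by step^2
        coeffs = savgol_coeffs(13, 2, deriv=2, delta=axis726.step)
        oracle = np.convolve(spec, coeffs[::-1], mode="valid")
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        # and the analytic second derivative is approximated in the interior
        analytic = -omega ** 2 * np.sin(omega * nu[6:-6])
        # a 13-point quadratic fit attenuates this frequency by ~11%,
        # so the analytic curve is only an approximate reference
        assert np.max(np.abs(out - analytic)) < 0.15 * omega ** 2

    def test_linearity(self, rng, axis726):
        x = rng.normal(size=(1, 1, len(axis726)))
        y = rng.normal(size=(1, 1, len(axis726)))
        cube = lambda d: SpectralCube(d, axis726)  # noqa: E731
        d = lambda c: second_derivative(c).absorbance  # noqa: E731
        np.testing.assert_allclose(
            d(cube(2.0 * x + 3.0 * y)),
            2.0 * d(cube(x)) + 3.0 * d(cube(y)), atol=1e-10)

    def test_too_few_bands_raises(self, random_cube):
        with pytest.raises(RangeError):
            second_derivative(random_cube, SgParams(13, 2, 2))


class TestVectorNormalize:
    def test_unit_norm_spectrum_unchanged(self, axis8):
        v = np.zeros(8)
        v[3] = 1.0
        cube = SpectralCube(v.reshape(1, 1, -1).copy(), axis8)
        out, ok = vector_normalize(cube)
        np.testing.assert_allclose(out.absorbance[0, 0], v, atol=1e-15)
        assert ok.all()

    def test_positive_scale_invariance_and_idempotence(self, rng, axis8):
        data = rng.uniform(0.1, 1.0, size=(3, 3, 8))
        cube = SpectralCube(data, axis8)
        scaled = SpectralCube(7.0 * data, axis8)
        out1, _ = vector_normalize(cube)
        out7, _ = vector_normalize(scaled)
        np.testing.assert_allclose(out1.absorbance, out7.absorbance, rtol=1e-12)
        again, _ = vector_normalize(out1)
        np.testing.assert_allclose(again.absorbance, out1.absorbance,
                                   rtol=1e-12)

    def test_norms_are_one(self, rng, axis8):
        cube = SpectralCube(rng.normal(size=(5, 5, 8)), axis8)
        out, ok = vector_normalize(cube)
        norms = np.linalg.norm(out.absorbance, axis=2)
        np.testing.assert_allclose(norms[ok], 1.0, atol=1e-12)

    def test_zero_norm_pixels_flagged(self, axis8):
        data = np.zeros((2, 1, 8))
        data[0, 0] = 1.0
        cube = SpectralCube(data, axis8)
        out, ok = vector_normalize(cube)
        assert ok[0, 0] and not ok[1, 0]
        np.testing.assert_array_equal(out.absorbance[1, 0], 0.0)


class TestBinPixels:
    def test_factor_one_is_identity(self, random_cube):
        out = bin_pixels(random_cube, 1)
        np.testing.assert_array_equal(out.absorbance, random_cube.absorbance)

    def test_constant_cube_stays_constant(self, axis8):
        cube = SpectralCube(np.full((6, 6, 8), 0.33), axis8)
        out = bin_pixels(cube, 3)
        assert out.shape == (2, 2, 8)
        np.testing.assert_allclose(out.absorbance, 0.33, rtol=1e-12)

    def test_matches_block_loop_oracle(self, rng, axis8):
        cube = SpectralCube(rng.normal(size=(4, 4, 8)), axis8, 1.1)
        out = bin_pixels(cube, 2)
        for r in range(2):
            for c in range(2):
                block = cube.absorbance[2 * r:2 * r + 2, 2 * c:2 * c + 2]
                np.testing.assert_allclose(out.absorbance[r, c],
                                           block.mean(axis=(0, 1)), rtol=1e-12)
        assert out.pixel_pitch == pytest.approx(2.2)

    def test_global_mean_preserved_when_even(self, rng, axis8):
        cube = SpectralCube(rng.normal(size=(8, 8, 8)), axis8)
        out = bin_pixels(cube, 4)
        np.testing.assert_allclose(out.absorbance.mean(axis=(0, 1)),
                                   cube.absorbance.mean(axis=(0, 1)),
                                   rtol=1e-10, atol=1e-12)

    def test_remainder_dropped(self, rng, axis8):
        cube = SpectralCube(rng.normal(size=(5, 7, 8)), axis8)
        out = bin_pixels(cube, 2)
        assert out.shape[:2] == (2, 3)

    def test_oversized_factor_raises(self, random_cube):
        with pytest.raises(RangeError):
            bin_pixels(random_cube, 99)
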
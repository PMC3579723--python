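"""Steerable G2 basis: kernels, steering identity, closed-form orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from axonfield import (
    RasterImage,
    basis_responses,
    build_filter_bank,
    dominant_orientation,
    steered_response,
)
from axonfield.errors import CalibrationError, InvalidParameterError, UndersamplingError
from axonfield.filters import FWHM_PER_SIGMA, BasisResponses, oriented_kernel
from axonfield.synth import make_stripe


class TestFilterBank:
    def test_three_zero_sum_kernels(self, unit_bank):
        kernels = [unit_bank.kernel_a, unit_bank.kernel_b, unit_bank.kernel_c]
        assert len(kernels) == 3
        for k in kernels:
            assert abs(k.sum()) <= 1e-10 * np.abs(k).sum()

    def test_kernel_a_rot90_is_kernel_c(self, unit_bank):
        assert np.array_equal(np.rot90(unit_bank.kernel_a), unit_bank.kernel_c)

    def test_support_radius_is_four_sigma(self, unit_bank):
        assert unit_bank.support_radius_px == int(np.ceil(4 * 1.8))
        assert unit_bank.kernel_a.shape == (2 * unit_bank.support_radius_px + 1,) * 2

    def test_fwhm_reading_shrinks_sigma(self):
        bank = build_filter_bank(1.8 * FWHM_PER_SIGMA, 1.0, sigma_is_fwhm=True)
        assert bank.sigma_px == pytest.approx(1.8)

    @pytest.mark.parametrize(
        "sigma,pixel,err",
        [
            (0.0, 1.0, InvalidParameterError),
            (-1.0, 1.0, InvalidParameterError),
            (1.8, 0.0, InvalidParameterError),
            (1.8, 4.0, UndersamplingError),  # sigma = 0.45 px
        ],
    )
    def test_invalid_parameters(self, sigma, pixel, err):
        with pytest.raises(err):
            build_filter_bank(sigma, pixel)


class TestBasisResponses:
    def test_constant_image_gives_zero_everywhere(self, unit_bank):
        img = RasterImage(np.full((40, 40), 7.3), 1.0)
        basis = basis_responses(img, unit_bank)
        for r in (basis.r_a, basis.r_b, basis.r_c):
            assert np.max(np.abs(r)) < 1e-9

    def test_autocorrelation_peak_matches_dot_product(self, unit_bank):
        # image = kernel_a embedded in zeros; response at the centre is the
        # kernel's inner product with itself
        k = unit_bank.kernel_a
        pad = 10
        img_arr = np.pad(k - k.min(), pad)  # keep intensities non-negative
        img = RasterImage(img_arr, 1.0)
        basis = basis_responses(img, unit_bank)
        centre = pad + unit_bank.support_radius_px
        oracle = float(np.sum(k * k))  # the constant offset sees a zero-sum kernel
        assert basis.r_a[centre, centre] == pytest.approx(oracle, rel=1e-9)

    def test_matches_naive_convolution_at_random_pixels(self, unit_bank, rng):
        img = RasterImage(rng.random((50, 50)) * 5.0, 1.0)
        basis = basis_responses(img, unit_bank)
        r = unit_bank.support_radius_px
        for _ in range(5):
            y, x = rng.integers(r, 50 - r, size=2)
            for kern, resp in (
                (unit_bank.kernel_a, basis.r_a),
                (unit_bank.kernel_b, basis.r_b),
                (unit_bank.kernel_c, basis.r_c),
            ):
                patch = img.pixels[y - r : y + r + 1, x - r : x + r + 1]
                naive = float(np.sum(patch * kern))  # even kernel: conv == corr
                assert resp[y, x] == pytest.approx(naive, abs=1e-9)

    def test_vertical_stripe_prefers_one_axis_kernel(self, unit_bank):
        img, _ = make_stripe(np.pi / 2, noise_sigma=0.0, size=(64, 64))
        basis = basis_responses(img, unit_bank)
        c = 32
        # a stripe along y varies along x: the theta=pi/2 detector (kernel_c)
        # dominates the theta=0 one on the centreline
        assert abs(basis.r_c[c, c]) > 10 * abs(basis.r_a[c, c])

    def test_pitch_mismatch_raises(self, unit_bank):
        img = RasterImage(np.zeros((10, 10)), 2.0)
        with pytest.raises(CalibrationError):
            basis_responses(img, unit_bank)


class TestSteering:
    def test_identity_against_closed_form(self, random_basis, rng):
        _, basis = random_basis
        a = 0.5 * (basis.r_a + basis.r_c)
        b = 0.5 * (basis.r_a - basis.r_c)
        c = -basis.r_b
        for theta in rng.uniform(0, np.pi, 50):
            steered = steered_response(basis, theta)
            closed = a + b * np.cos(2 * theta) + c * np.sin(2 * theta)
            assert np.max(np.abs(steered - closed)) <= 1e-10 * np.max(np.abs(steered))

    def test_axis_angles_return_basis_responses(self, random_basis):
        _, basis = random_basis
        assert np.array_equal(steered_response(basis, 0.0), basis.r_a)
        np.testing.assert_allclose(
            steered_response(basis, np.pi / 2), basis.r_c, atol=1e-12
        )

    def test_matches_explicitly_rotated_kernel(self, unit_bank, random_basis):
        img, basis = random_basis
        for theta in (np.pi / 4, 1.1):
            kern = oriented_kernel(unit_bank, theta)
            direct = ndimage.correlate(img.pixels, kern, mode="reflect")
            steered = steered_response(basis, theta)
            rel_rms = np.sqrt(np.mean((steered - direct) ** 2) / np.mean(direct**2))
            assert rel_rms <= 0.01

    def test_nonfinite_angle_rejected(self, random_basis):
        _, basis = random_basis
        with pytest.raises(InvalidParameterError):
            steered_response(basis, np.nan)


class TestDominantOrientation:
    def _single_pixel_basis(self, ra, rb, rc):
        shape = (3, 3)
        return BasisResponses(
            np.full(shape, float(ra)),
            np.full(shape, float(rb)),
            np.full(shape, float(rc)),
            support_radius_px=0,
        )

    def test_pure_r_a_gives_zero_angle_unit_response(self):
        field = dominant_orientation(self._single_pixel_basis(1, 0, 0))
        assert field.theta[1, 1] == pytest.approx(0.0)
        assert field.response[1, 1] == pytest.approx(1.0)

    def test_isotropic_tie_break_angle_zero(self):
        field = dominant_orientation(self._single_pixel_basis(0.7, 0, 0.7))
        assert field.theta[1, 1] == pytest.approx(0.0)
        assert field.response[1, 1] == pytest.approx(0.7)

    def test_theta_in_axial_range(self, random_basis):
        _, basis = random_basis
        field = dominant_orientation(basis)
        assert np.all(field.theta >= 0) and np.all(field.theta < np.pi)

    def test_border_band_masked(self, random_basis):
        _, basis = random_basis
        field = dominant_orientation(basis)
        r = basis.support_radius_px
        assert not field.mask[:r, :].any()
        assert field.mask[r:-r, r:-r].all()

    def test_ridge_orientation_matches_dense_sweep(self, unit_bank):
        img, truth = make_stripe(np.radians(30), noise_sigma=0.0)
        basis = basis_responses(img, unit_bank)
        field = dominant_orientation(basis)
        sweep = np.linspace(0, np.pi, 720, endpoint=False)
        centre = truth.centreline_xy[::40]
        for x, y in centre:
            xi, yi = int(round(x)), int(round(y))
            if not field.mask[yi, xi]:
                continue
            responses = [steered_response_at(basis, t, yi, xi) for t in sweep]
            best = sweep[int(np.argmax(responses))]
            diff = abs(field.theta[yi, xi] - best) % np.pi
            assert min(diff, np.pi - diff) <= np.pi / 720 + 1e-9
            diff30 = abs(field.theta[yi, xi] - np.radians(30)) % np.pi
            assert np.degrees(min(diff30, np.pi - diff30)) <= 2.0

    def test_rotation_equivariance_quarter_turn(self, unit_bank, rng):
        img = RasterImage(rng.random((40, 40)) * 3.0, 1.0)
        field = dominant_orientation(basis_responses(img, unit_bank))
        rot_img = RasterImage(np.rot90(img.pixels), 1.0)
        rot_field = dominant_orientation(basis_responses(rot_img, unit_bank))
        # rotating the image by 90 deg CCW sends orientation theta to
        # theta - pi/2 (mod pi) in the rotated frame
        inner = (slice(15, 25), slice(15, 25))
        expected = np.mod(np.rot90(field.theta) - np.pi / 2, np.pi)
        diff = np.abs(np.mod(rot_field.theta[inner] - expected[inner] + np.pi / 2, np.pi) - np.pi / 2)
        assert diff.max() < 1e-9

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_intensity_scale_invariance(self, scale):
        gen = np.random.default_rng(3)
        pixels = gen.random((32, 32)) * 4.0
        bank = build_filter_bank(1.8, 1.0)
        f1 = dominant_orientation(basis_responses(RasterImage(pixels, 1.0), bank))
        f2 = dominant_orientation(
            basis_responses(RasterImage(pixels * scale, 1.0), bank)
        )
        np.testing.assert_allclose(f2.response, f1.response * scale, rtol=1e-9)
        diff = np.abs(np.mod(f2.theta - f1.theta + np.pi / 2, np.pi) - np.pi / 2)
        assert diff.max() < 1e-7


def steered_response_at(basis, theta, y, x):
    c, s = np.cos(theta), np.sin(theta)
    return (
        c * c * basis.r_a[y, x] - 2 * c * s * basis.r_b[y, x] + s * s * basis.r_c[y, x]
    )
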
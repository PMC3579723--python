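"""Direction disambiguation, normalized-convolution smoothing, curl curvature."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from axonfield import (
    basis_responses,
    build_filter_bank,
    curvature_from_curl,
    dominant_orientation,
    median_threshold,
    nonmax_suppress,
    second_nonmax,
    smooth_direction_field,
    to_direction_field,
)
from axonfield.field import DirectionField, resolve_directions
from axonfield.filters import OrientationField
from axonfield.pipeline import analyze_image
from axonfield.synth import PhantomSpec, make_phantom_chiasm, make_stripe
from axonfield.validation import ring_curvature


def _orientation(theta, mask=None, response=None):
    theta = np.asarray(theta, float)
    if response is None:
        response = np.ones_like(theta)
    if mask is None:
        mask = np.ones(theta.shape, bool)
    return OrientationField(theta, np.asarray(response, float), mask)


class TestToDirectionField:
    def test_pixel_right_of_eye_points_further_right(self):
        field = _orientation(np.zeros((3, 5)))
        out = to_direction_field(field, injection_point=(0.0, 1.0))
        assert out.direction[1, 3] == pytest.approx(0.0)

    def test_orthogonal_radial_component_uses_tie_break(self):
        # pixel straight right of the eye with a vertical orientation: both
        # candidates are orthogonal to the radial line; the vertical
        # tie-break keeps +y
        field = _orientation(np.full((3, 5), np.pi / 2))
        out = to_direction_field(field, injection_point=(0.0, 1.0))
        assert out.direction[1, 3] == pytest.approx(np.pi / 2)

    def test_direction_mod_pi_preserves_orientation(self, rng):
        theta = rng.uniform(0, np.pi, (20, 20))
        out = to_direction_field(_orientation(theta), (5.0, 5.0))
        diff = np.abs(np.mod(out.direction, np.pi) - theta)
        assert np.max(np.minimum(diff, np.pi - diff)) < 1e-9

    def test_mirrored_eye_flips_every_generic_direction(self, rng):
        theta = rng.uniform(0.01, np.pi - 0.01, (21, 21))
        field = _orientation(theta)
        a = to_direction_field(field, (-50.0, 10.0))
        b = to_direction_field(field, (70.0, 10.0))
        dot = np.cos(a.direction - b.direction)
        # opposite eyes: directions anti-align except near the tie locus
        assert np.mean(dot < 0) > 0.95

    def test_phantom_travel_directions_recovered(self):
        # well-separated bundle so crossing artefacts do not confound the sense
        spec = PhantomSpec(
            n_trajectories=14, band_tail_scale=0.05, band_depth_max=0.1, seed=9
        )
        img, landmarks, truth = make_phantom_chiasm(spec)
        result = analyze_image(img, landmarks.left_eye)
        vec = result.vectors
        tree = cKDTree(truth.points_xy)
        dist, idx = tree.query(vec[["x_px", "y_px"]].to_numpy())
        near = dist < 2.0
        true_dir = truth.direction_rad[idx[near]]
        err = np.abs(
            np.mod(vec["direction_rad"].to_numpy()[near] - true_dir + np.pi, 2 * np.pi)
            - np.pi
        )
        assert np.mean(err < np.pi / 2) >= 0.99


class TestSmoothing:
    def test_uniform_field_unchanged(self):
        field = DirectionField(np.full((30, 30), 1.234), np.ones((30, 30), bool))
        out = smooth_direction_field(field, 10.0, 1.0)
        assert np.max(np.abs(out.direction[out.mask] - 1.234)) < 1e-9

    def test_single_flipped_outlier_pulled_to_consensus(self):
        direction = np.full((32, 32), 0.3)
        direction[16, 16] += np.pi  # one anti-parallel vector among ~1000
        field = DirectionField(direction, np.ones((32, 32), bool))
        out = smooth_direction_field(field, 5.0, 1.0)
        diff = np.abs(np.mod(out.direction[16, 16] - 0.3 + np.pi, 2 * np.pi) - np.pi)
        assert np.degrees(diff) < 5.0

    def test_matches_direct_normalized_convolution(self, rng):
        from scipy import ndimage

        direction = rng.uniform(0, 2 * np.pi, (24, 24))
        mask = rng.random((24, 24)) > 0.5
        field = DirectionField(direction, mask)
        sigma = 3.0
        out = smooth_direction_field(field, sigma, 1.0)
        w = mask.astype(float)
        cx = ndimage.gaussian_filter(w * np.cos(direction), sigma)
        sx = ndimage.gaussian_filter(w * np.sin(direction), sigma)
        oracle = np.mod(np.arctan2(sx, cx), 2 * np.pi)
        diff = np.abs(np.mod(out.direction[mask] - oracle[mask] + np.pi, 2 * np.pi) - np.pi)
        assert diff.max() < 1e-9

    def test_two_domain_boundary_transition_is_monotone(self):
        # 45 deg jump across a vertical boundary: smoothed angle sweeps
        # monotonically through the transition, width ~ sigma
        direction = np.where(np.arange(64)[None, :] < 32, 0.0, np.pi / 4)
        direction = np.tile(direction, (20, 1))
        field = DirectionField(direction, np.ones((20, 64), bool))
        out = smooth_direction_field(field, 4.0, 1.0)
        profile = out.direction[10, 8:-8]
        assert np.all(np.diff(profile) >= -1e-9)
        interior = profile[(profile > 0.05) & (profile < np.pi / 4 - 0.05)]
        assert 4 <= interior.size <= 16  # transition ~ sigma, not the whole row

    def test_empty_mask_returned_unchanged(self):
        field = DirectionField(np.zeros((5, 5)), np.zeros((5, 5), bool))
        out = smooth_direction_field(field, 5.0, 1.0)
        assert not out.mask.any()


class TestCurvature:
    def _circle_field(self, shape=(200, 200), sense=1.0):
        cy = cx = shape[0] // 2
        yy, xx = np.indices(shape, float)
        phi = np.arctan2(yy - cy, xx - cx)
        rho = np.hypot(yy - cy, xx - cx)
        direction = np.mod(phi + sense * np.pi / 2, 2 * np.pi)
        mask = (rho > 12) & (rho < 92)
        return DirectionField(direction, mask), rho

    def test_uniform_direction_zero_curvature(self):
        field = DirectionField(np.full((20, 20), 0.7), np.ones((20, 20), bool))
        curv = curvature_from_curl(field, 1.0)
        assert np.nanmax(np.abs(curv.kappa[curv.mask])) < 1e-9

    @pytest.mark.parametrize("radius", [20.0, 50.0, 80.0])
    def test_concentric_circles_give_inverse_radius(self, radius):
        field, rho = self._circle_field()
        curv = curvature_from_curl(field, 1.0)
        ring = curv.mask & (np.abs(rho - radius) < 1.0)
        med = np.nanmedian(np.abs(curv.kappa[ring]))
        assert med == pytest.approx(1.0 / radius, rel=0.10)

    def test_traversal_sense_flips_sign_not_magnitude(self):
        ccw, rho = self._circle_field(sense=1.0)
        cw, _ = self._circle_field(sense=-1.0)
        k_ccw = curvature_from_curl(ccw, 1.0)
        k_cw = curvature_from_curl(cw, 1.0)
        ring = k_ccw.mask & k_cw.mask & (np.abs(rho - 50) < 1)
        np.testing.assert_allclose(k_ccw.kappa[ring], -k_cw.kappa[ring], atol=1e-9)

    def test_curvature_vector_orthogonal_to_direction(self):
        field, rho = self._circle_field()
        curv = curvature_from_curl(field, 1.0)
        sel = curv.mask & (np.abs(curv.kappa) > 1e-6)
        dot = np.cos(curv.curvature_angle[sel] - field.direction[sel])
        assert np.max(np.abs(dot)) < 1e-9

    def test_magnitude_invariant_under_quarter_rotation(self):
        field, _ = self._circle_field()
        curv = curvature_from_curl(field, 1.0)
        rot = DirectionField(
            np.mod(np.rot90(field.direction) - np.pi / 2, 2 * np.pi),
            np.rot90(field.mask).copy(),
        )
        curv_rot = curvature_from_curl(rot, 1.0)
        a = np.abs(np.rot90(curv.kappa))
        b = np.abs(curv_rot.kappa)
        sel = np.rot90(curv.mask) & curv_rot.mask
        # drop pixels on the rotated mask edge where one-sided stencils differ
        interior = sel & np.roll(sel, 1, 0) & np.roll(sel, -1, 0)
        interior &= np.roll(sel, 1, 1) & np.roll(sel, -1, 1)
        np.testing.assert_allclose(a[interior], b[interior], atol=1e-9)

    def test_pixel_size_scales_curvature(self):
        field, rho = self._circle_field()
        k1 = curvature_from_curl(field, 1.0)
        k2 = curvature_from_curl(field, 2.0)
        ring = k1.mask & (np.abs(rho - 50) < 1)
        np.testing.assert_allclose(k2.kappa[ring], k1.kappa[ring] / 2.0, atol=1e-12)

    def test_pipeline_recovers_ring_curvature_monotone(self):
        result = ring_curvature(seed=1)
        meds = [result[r]["median_kappa"] for r in (20.0, 50.0, 100.0)]
        assert all(result[r]["rel_err"] <= 0.15 for r in (20.0, 50.0, 100.0))
        assert meds[0] > meds[1] > meds[2]


class TestSecondNonmax:
    def test_thin_unsmoothed_field_unchanged(self):
        img, _ = make_stripe(np.radians(40), noise_sigma=1.0, seed=6)
        bank = build_filter_bank(1.8, 1.0)
        field = median_threshold(
            img, nonmax_suppress(dominant_orientation(basis_responses(img, bank)))
        )
        direction = to_direction_field(field, (0.0, 0.0))
        mask2 = second_nonmax(direction, field.response)
        assert np.array_equal(mask2, field.mask)

    def test_thick_stripe_reduced_to_thin_centreline(self):
        img, truth = make_stripe(np.radians(25), noise_sigma=0.0)
        bank = build_filter_bank(1.8, 1.0)
        field = dominant_orientation(basis_responses(img, bank))  # no first NMS
        direction = to_direction_field(field, (0.0, 64.0))
        mask2 = second_nonmax(direction, field.response)
        ys, xs = np.nonzero(mask2)
        u = np.array([np.cos(np.radians(25)), np.sin(np.radians(25))])
        d = -(xs - 64.0) * u[1] + (ys - 64.0) * u[0]
        near = np.abs(d) <= 3
        assert np.ptp(d[near]) <= 2.0 or np.percentile(np.abs(d[near]), 95) <= 1.0

    def test_resolve_directions_honours_reference(self, rng):
        theta = rng.uniform(0, np.pi, (10, 10))
        ref = rng.uniform(0, 2 * np.pi, (10, 10))
        out = resolve_directions(_orientation(theta), ref)
        dot = np.cos(out.direction - ref)
        assert np.all(dot >= -1e-12)
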
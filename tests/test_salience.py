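"""Row curvature, lagged variation, normalisation, thresholding, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epflow.io_cine import Orientation, ROIRect
from epflow.salience import (
    DeltaTauField,
    RowCurvatures,
    SalienceField,
    apply_threshold,
    compute_row_curvatures,
    curvature_variation,
    fit_row_curvature,
    normalize_magnitude,
    render_overlay,
    sigmoid_weights,
    travel_direction_signs,
)
from epflow.tracking import TrajectorySet, generate_feature_grid


def _row_inputs(transverse):
    """One-frame row slices for an 8-point row at 15 px axial spacing."""
    axial = np.arange(8, dtype=float)[None, :] * 15.0
    trans = np.asarray(transverse, dtype=float)[None, :]
    valid = np.ones((1, 8), dtype=bool)
    return axial, trans, valid


class TestRowCurvature:
    @pytest.mark.parametrize("slope,offset", [(0.0, 0.0), (0.3, -2.0), (-1.5, 4.0)])
    def test_collinear_points_have_zero_curvature(self, slope, offset):
        axial, trans, valid = _row_inputs(slope * np.arange(8) * 15.0 + offset)
        tau, ok = fit_row_curvature(axial, trans, valid)
        assert ok[0]
        assert tau[0] == pytest.approx(0.0, abs=1e-12)

    def test_parabola_recovers_twice_the_quadratic_coefficient(self):
        x = np.arange(8) * 15.0
        axial, trans, valid = _row_inputs(0.01 * (x - 50.0) ** 2)
        tau, ok = fit_row_curvature(axial, trans, valid)
        assert ok[0]
        assert tau[0] == pytest.approx(0.02, rel=1e-9)

    def test_under_three_points_is_invalid_not_an_error(self):
        axial, trans, valid = _row_inputs(np.zeros(8))
        valid[0, 2:] = False
        tau, ok = fit_row_curvature(axial, trans, valid)
        assert not ok[0]

    def test_rigid_translation_keeps_all_rows_straight(self):
        """Whole-grid translation (probe slip) never produces curvature."""
        grid = generate_feature_grid(ROIRect(10, 10, 100, 60), spacing=15)
        n_t = 12
        coords = np.repeat(grid.initial_coords[None], n_t, axis=0)
        drift = np.linspace(0, 5, n_t)  # diagonal drift up to 5 px
        coords = coords + drift[:, None, None, None]
        traj = TrajectorySet(
            coords=coords,
            displacements=np.diff(coords, axis=0),
            valid_mask=np.ones(coords.shape[:-1], dtype=bool),
        )
        curv = compute_row_curvatures(traj, grid, Orientation.CERVIX_LEFT)
        assert curv.fit_valid.all()
        assert np.abs(curv.tau).max() < 1e-9


def _curv(tau, valid=None):
    tau = np.asarray(tau, dtype=float)
    if valid is None:
        valid = np.ones_like(tau, dtype=bool)
    return RowCurvatures(tau=tau, fit_valid=valid)


class TestCurvatureVariation:
    def test_constant_curvature_has_zero_variation(self):
        field = curvature_variation(_curv(np.full((20, 3), 0.7)), lag=5)
        np.testing.assert_allclose(field.delta_tau, 0.0)
        assert (field.sign == 0).all()

    def test_single_spike_appears_with_positive_sign(self):
        tau = np.zeros((20, 1))
        tau[10, 0] = 0.2
        field = curvature_variation(_curv(tau), lag=5)
        assert field.delta_tau[10, 0] == pytest.approx(0.2)
        assert field.sign[10, 0] == 1
        assert field.magnitude[10, 0] == pytest.approx(0.2)
        # five frames later the spike is the lagged reference: negative swing
        assert field.delta_tau[15, 0] == pytest.approx(-0.2)
        assert field.sign[15, 0] == -1

    def test_early_frames_subtract_the_first_frame(self):
        rng = np.random.default_rng(7)
        tau = rng.normal(size=(12, 2))
        field = curvature_variation(_curv(tau), lag=5)
        np.testing.assert_allclose(field.delta_tau[3], tau[3] - tau[0])
        np.testing.assert_allclose(field.delta_tau[0], 0.0)
        np.testing.assert_allclose(field.delta_tau[7], tau[7] - tau[2])

    def test_sign_magnitude_product_reconstructs_delta(self):
        rng = np.random.default_rng(8)
        tau = rng.normal(size=(30, 4))
        field = curvature_variation(_curv(tau), lag=5)
        np.testing.assert_allclose(field.sign * field.magnitude, field.delta_tau)

    def test_lag_below_one_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            curvature_variation(_curv(np.zeros((5, 2))), lag=0)


def _field(magnitudes, valid=None):
    mag = np.asarray(magnitudes, dtype=float)
    if valid is None:
        valid = np.ones_like(mag, dtype=bool)
    return DeltaTauField(
        delta_tau=mag.copy(), magnitude=np.abs(mag), sign=np.sign(mag).astype(np.int8),
        lag=5, valid=valid,
    )


class TestNormalisation:
    def test_affine_fixed_points(self):
        sal = normalize_magnitude(_field([[0.0, 0.5, 1.0]]), min_magnitude=0.0)
        np.testing.assert_allclose(sal.y0, [[0.0, 0.5, 1.0]])

    def test_range_is_exactly_unit_on_nondegenerate_input(self, rng):
        mags = rng.uniform(0.001, 0.01, size=(50, 6))
        sal = normalize_magnitude(_field(mags), min_magnitude=0.0)
        assert sal.y0.min() == 0.0
        assert sal.y0.max() == 1.0
        assert ((sal.y0 >= 0) & (sal.y0 <= 1)).all()

    def test_equal_magnitudes_normalise_to_zero(self):
        sal = normalize_magnitude(_field(np.full((10, 3), 0.4)))
        np.testing.assert_allclose(sal.y0, 0.0)

    def test_noise_floor_suppresses_motionless_clips(self):
        # everything below the floor: relative contrast must not be stretched
        sal = normalize_magnitude(_field([[0.0, 1e-5, 2e-5]]), min_magnitude=2e-4)
        np.testing.assert_allclose(sal.y0, 0.0)

    def test_invalid_entries_get_zero(self):
        valid = np.array([[True, True, False]])
        sal = normalize_magnitude(_field([[0.0, 0.5, 0.9]], valid), min_magnitude=0.0)
        assert sal.y0[0, 2] == 0.0


class TestThresholdAndSigmoid:
    def test_boundary_is_strictly_non_salient(self):
        sal = apply_threshold(normalize_magnitude(_field([[0.0, 0.6, 1.0]]), 0.0), alpha=0.6)
        np.testing.assert_allclose(sal.y1, [[-0.6, 0.0, 0.4]])
        assert sal.salient_mask.tolist() == [[False, False, True]]

    def test_alpha_outside_unit_interval_rejected(self):
        sal = normalize_magnitude(_field([[0.0, 1.0]]), 0.0)
        for bad in (-0.1, 1.5):
            with pytest.raises(ValueError, match="alpha"):
                apply_threshold(sal, alpha=bad)

    def test_sigmoid_midpoint_and_closed_form(self):
        sal = apply_threshold(normalize_magnitude(_field([[0.0, 0.6, 1.0]]), 0.0), 0.6)
        out = sigmoid_weights(sal, beta=10.0)
        assert out.y2[0, 1] == pytest.approx(0.5)  # y1 = 0
        assert out.y2[0, 2] == pytest.approx(1.0 / (1.0 + np.exp(-4.0)))
        big = sigmoid_weights(sal, beta=1e4)
        assert big.y2[0, 2] == pytest.approx(1.0, abs=1e-12)  # beta -> inf limit

    def test_beta_must_be_positive(self):
        sal = apply_threshold(normalize_magnitude(_field([[0.0, 1.0]]), 0.0), 0.6)
        with pytest.raises(ValueError, match="beta"):
            sigmoid_weights(sal, beta=0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        y1a=st.floats(-1, 1), y1b=st.floats(-1, 1),
        beta=st.floats(0.1, 100),
    )
    def test_sigmoid_strictly_increasing_in_y1(self, y1a, y1b, beta):
        sal = SalienceField(
            y0=np.zeros((1, 2)), valid=np.ones((1, 2), bool),
            alpha=0.5, y1=np.array([[y1a, y1b]]),
        )
        y2 = sigmoid_weights(sal, beta).y2
        if abs(y1a - y1b) * beta < 1e-9:  # below float resolution of the logistic
            return
        if y1a < y1b:
            assert y2[0, 0] < y2[0, 1]
        else:
            assert y2[0, 0] > y2[0, 1]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(alphas=st.lists(st.floats(0, 1), min_size=2, max_size=2))
    def test_salient_set_shrinks_as_alpha_grows(self, rng, alphas):
        mags = rng.uniform(0, 0.01, size=(20, 4))
        sal = normalize_magnitude(_field(mags), 0.0)
        lo, hi = sorted(alphas)
        m_lo = apply_threshold(sal, lo).salient_mask
        m_hi = apply_threshold(sal, hi).salient_mask
        assert (m_hi <= m_lo).all()


class TestSignSymmetry:
    def test_negating_transverse_motion_flips_tau_but_not_y0(self):
        grid = generate_feature_grid(ROIRect(0, 0, 120, 60), spacing=15)
        n_t = 15
        rng = np.random.default_rng(9)
        bump = rng.normal(scale=2.0, size=(n_t, grid.rows, grid.cols))

        def build(sign):
            coords = np.repeat(grid.initial_coords[None], n_t, axis=0).astype(float)
            coords[..., 1] += sign * bump
            return TrajectorySet(
                coords=coords, displacements=np.diff(coords, axis=0),
                valid_mask=np.ones(coords.shape[:-1], dtype=bool),
            )

        cp = compute_row_curvatures(build(+1), grid, Orientation.CERVIX_LEFT)
        cm = compute_row_curvatures(build(-1), grid, Orientation.CERVIX_LEFT)
        np.testing.assert_allclose(cm.tau, -cp.tau, atol=1e-12)
        fp = curvature_variation(cp, 5)
        fm = curvature_variation(cm, 5)
        np.testing.assert_array_equal(fm.sign, -fp.sign)
        np.testing.assert_allclose(
            normalize_magnitude(fm, 0.0).y0, normalize_magnitude(fp, 0.0).y0
        )


class TestTravelDirection:
    def test_forward_moving_pattern_is_positive(self):
        """A transverse bump translating toward image-left is 'forward'."""
        grid = generate_feature_grid(ROIRect(0, 0, 150, 60), spacing=15)
        n_t = 20
        coords = np.repeat(grid.initial_coords[None], n_t, axis=0).astype(float)
        xs = grid.initial_coords[0, :, 0]
        for t in range(n_t):
            center = 140.0 - 6.0 * t  # moves left 6 px/frame
            coords[t, ..., 1] += 4.0 * np.exp(-0.5 * ((xs - center) / 25.0) ** 2)[None, :]
        traj = TrajectorySet(
            coords=coords, displacements=np.diff(coords, axis=0),
            valid_mask=np.ones(coords.shape[:-1], dtype=bool),
        )
        signs = travel_direction_signs(traj, grid, Orientation.CERVIX_LEFT, lag=5)
        mid = signs[8:16]
        assert (mid == 1).mean() > 0.9
        # reverse time: backward
        rev = TrajectorySet(
            coords=coords[::-1].copy(),
            displacements=np.diff(coords[::-1], axis=0),
            valid_mask=np.ones(coords.shape[:-1], dtype=bool),
        )
        rsigns = travel_direction_signs(rev, grid, Orientation.CERVIX_LEFT, lag=5)
        assert (rsigns[8:16] == -1).mean() > 0.9


class TestRenderOverlay:
    def _salience(self, weights):
        y2 = np.asarray(weights, dtype=float)[None, :]
        n = y2.shape[1]
        return SalienceField(
            y0=np.zeros((1, n)), valid=np.ones((1, n), bool), alpha=0.6,
            y1=np.zeros((1, n)), salient_mask=np.zeros((1, n), bool),
            beta=10.0, y2=y2,
        )

    def test_subthreshold_rows_leave_the_frame_untouched(self, rng):
        roi = ROIRect(10, 10, 60, 45)
        grid = generate_feature_grid(roi, spacing=15)
        frame = rng.uniform(0, 255, size=(64, 80))
        sal = self._salience(np.full(grid.rows, 0.5))  # y1 = 0 baseline
        out = render_overlay(frame, sal, grid, 0, roi)
        np.testing.assert_allclose(out, np.repeat(frame[..., None], 3, axis=-1))

    def test_fully_salient_row_saturates_red_band(self):
        roi = ROIRect(10, 10, 60, 45)
        grid = generate_feature_grid(roi, spacing=15)
        frame = np.full((64, 80), 120.0)
        weights = np.full(grid.rows, 0.5)
        weights[1] = 0.999  # row at y = 25
        sal = self._salience(weights)
        out = render_overlay(frame, sal, grid, 0, roi, color=(255, 0, 0))
        assert out[25, 30, 0] == 255.0  # saturated red on the salient row
        assert out[25, 30, 1] == 120.0  # green/blue untouched
        assert out[5, 5, 0] == 120.0  # outside ROI untouched

    def test_output_clipped_to_byte_range(self, rng):
        roi = ROIRect(0, 0, 60, 45)
        grid = generate_feature_grid(roi, spacing=15)
        frame = rng.uniform(0, 255, size=(60, 60))
        sal = self._salience(rng.uniform(0.0, 1.0, size=grid.rows))
        out = render_overlay(frame, sal, grid, 0, roi)
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_non_grayscale_frame_rejected(self):
        roi = ROIRect(0, 0, 60, 45)
        grid = generate_feature_grid(roi, spacing=15)
        sal = self._salience(np.full(grid.rows, 0.5))
        with pytest.raises(ValueError, match="grayscale"):
            render_overlay(np.zeros((10, 10, 3)), sal, grid, 0, roi)
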
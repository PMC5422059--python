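"""ZUPT integration, drift compensation, displacement, calibration."""

import numpy as np
import pytest

from branchnav.ins_nav import (
    compensate_drift,
    compute_kinematics,
    fit_calibration,
    integrate_displacement,
    integrate_velocity,
    validate_calibration,
)
from branchnav.motion_detect import MovementSegment, StaticMask
from branchnav.synthgen import WalkSpec, gen_walk_trace, truth_mask
from branchnav.trace_io import ImuTrace
from branchnav.evaluate import walk_trials


def _trace_with_mask(acc_y: np.ndarray, moving: np.ndarray):
    n = acc_y.size
    trace = ImuTrace(
        t=0.01 * np.arange(n),
        acc=np.column_stack([np.zeros(n), acc_y, np.zeros(n)]),
        gyro=np.zeros((n, 3)),
        orient=np.zeros((n, 3)),
        mag=np.zeros((n, 3)),
        gps_lat=np.full(n, np.nan),
        gps_lon=np.full(n, np.nan),
        mode="NM",
    )
    segs = []
    padded = np.diff(np.concatenate(([0], moving.astype(np.int8), [0])))
    for i0, i1 in zip(np.flatnonzero(padded == 1), np.flatnonzero(padded == -1)):
        segs.append(MovementSegment(int(i0), int(i1), i0 * 0.01, i1 * 0.01))
    return trace, StaticMask(moving=moving, segments=segs, thd_used={})


class TestIntegrateVelocity:
    def test_constant_acceleration(self):
        moving = np.zeros(300, dtype=bool)
        moving[100:200] = True
        acc = np.where(moving, 1.0, 0.0)
        trace, mask = _trace_with_mask(acc, moving)
        v = integrate_velocity(trace, mask)
        assert v[199, 1] == pytest.approx(1.0)
        assert np.all(v[~moving] == 0)

    def test_all_static_is_identically_zero(self):
        trace, mask = _trace_with_mask(np.ones(200), np.zeros(200, dtype=bool))
        assert not integrate_velocity(trace, mask).any()

    def test_full_sine_period_returns_to_zero(self):
        moving = np.zeros(400, dtype=bool)
        moving[100:300] = True  # 2 s = one period at 0.5 Hz
        tt = (np.arange(400) - 99) * 0.01
        acc = np.where(moving, np.cos(2 * np.pi * 0.5 * tt), 0.0)
        trace, mask = _trace_with_mask(acc, moving)
        v = integrate_velocity(trace, mask)
        assert abs(v[299, 1]) < 1e-6

    def test_zupt_across_idle_gap(self):
        """No drift accumulates between two movements."""
        moving = np.zeros(600, dtype=bool)
        moving[100:200] = True
        moving[400:500] = True
        acc = np.where(moving, 0.5, 0.3)  # idle acc is masked away
        trace, mask = _trace_with_mask(acc, moving)
        v = integrate_velocity(trace, mask)
        assert np.all(v[200:400] == 0)
        assert v[400, 1] == pytest.approx(0.5 * 0.01)  # restarted from zero

    def test_length_mismatch(self):
        trace, mask = _trace_with_mask(np.zeros(100), np.zeros(100, dtype=bool))
        mask.moving = np.zeros(99, dtype=bool)
        with pytest.raises(ValueError):
            integrate_velocity(trace, mask)


class TestCompensateDrift:
    def test_slope_from_final_velocity(self):
        n = 201  # elapsed 2 s
        v = np.linspace(0, 0.2, n)[:, None]
        seg = MovementSegment(0, n, 0.0, n * 0.01)
        v_comp, m = compensate_drift(v, seg, 0.01)
        assert m[0] == pytest.approx(0.1)
        assert v_comp[-1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_pure_drift_line_vanishes(self):
        n = 151
        v = np.linspace(0, 0.3, n)[:, None]
        seg = MovementSegment(0, n, 0.0, n * 0.01)
        v_comp, _ = compensate_drift(v, seg, 0.01)
        np.testing.assert_allclose(v_comp, 0.0, atol=1e-12)

    def test_triangular_profile_unchanged_when_no_drift(self):
        n = 201
        v = np.concatenate([np.linspace(0, 0.5, 101), np.linspace(0.5, 0, 100)])[:, None]
        seg = MovementSegment(0, n, 0.0, n * 0.01)
        v_comp, m = compensate_drift(v, seg, 0.01)
        assert m[0] == pytest.approx(0.0)
        np.testing.assert_allclose(v_comp, v, atol=1e-12)

    def test_end_velocity_zero_for_random_profiles(self, rng):
        """Contract: every compensated segment ends at exactly zero."""
        for _ in range(20):
            n = int(rng.integers(50, 400))
            v = np.cumsum(rng.normal(0, 0.01, (n, 2)), axis=0)
            v -= v[0]
            seg = MovementSegment(0, n, 0.0, n * 0.01)
            v_comp, _ = compensate_drift(v, seg, 0.01)
            np.testing.assert_allclose(v_comp[-1], 0.0, atol=1e-9)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            compensate_drift(np.zeros((1, 2)), MovementSegment(0, 1, 0.0, 0.01), 0.01)


class TestDisplacement:
    def test_triangular_area_with_calibration(self):
        v = np.concatenate([np.linspace(0, 0.5, 100, endpoint=False), np.linspace(0.5, 0, 100)])
        raw, cal = integrate_displacement(v[:, None], 0.01, factor=1.4735)
        assert raw[0] == pytest.approx(0.5, abs=0.01)
        assert cal[0] == pytest.approx(1.4735 * raw[0])

    def test_identity_factor(self):
        v = np.abs(np.sin(np.linspace(0, 3, 200)))[:, None]
        raw, cal = integrate_displacement(v, 0.01, factor=1.0)
        np.testing.assert_allclose(raw, cal)

    def test_zero_velocity(self):
        raw, cal = integrate_displacement(np.zeros((100, 2)), 0.01)
        assert not raw.any() and not cal.any()

    def test_time_reversal_negates_displacement(self, rng):
        v = rng.normal(0, 0.2, (150, 2))
        raw_f, _ = integrate_displacement(v, 0.01, 1.0)
        raw_b, _ = integrate_displacement(-v[::-1], 0.01, 1.0)
        np.testing.assert_allclose(raw_b, -raw_f, atol=1e-12)


class TestNoiselessRecovery:
    def test_one_meter_step_exact(self):
        """Vibration-free 1 m step integrates back to 1.000 m."""
        spec = WalkSpec(
            step_lengths=[1.0], accel_sensitivity=1.0, noise_idle=1e-12,
            bias_bound=0.0, gait_amp=0.0, sway_amp=0.0, jolt_amp=0.0,
            noise_move=0.0, seed=3,
        )
        trace, truth = gen_walk_trace(spec)
        profile = compute_kinematics(trace, truth_mask(trace, truth), factor=1.0)
        assert profile.disp.sum(axis=0)[1] == pytest.approx(1.0, abs=1e-3)

    def test_sensitivity_deficit_is_linear(self):
        """Deficit 1/1.4735 halves nothing: raw = L/1.4735, calibrated = L."""
        spec = WalkSpec(
            step_lengths=[2.0], noise_idle=1e-12, bias_bound=0.0,
            gait_amp=0.0, sway_amp=0.0, jolt_amp=0.0, noise_move=0.0, seed=3,
        )
        trace, truth = gen_walk_trace(spec)
        profile = compute_kinematics(trace, truth_mask(trace, truth), factor=1.4735)
        assert profile.disp.sum(axis=0)[1] == pytest.approx(2.0 / 1.4735, abs=2e-3)
        assert profile.disp_cal.sum(axis=0)[1] == pytest.approx(2.0, abs=3e-3)


class TestEndVelocityContractOnGenerator:
    def test_compensated_velocity_ends_at_zero_every_segment(self):
        for seed in (0, 1, 2):
            trace, _ = gen_walk_trace(WalkSpec(step_lengths=[0.5, 1.5, 3.0], seed=seed))
            from branchnav.motion_detect import build_mask

            mask = build_mask(trace, mode="NM")
            profile = compute_kinematics(trace, mask)
            for seg in mask.segments:
                np.testing.assert_allclose(profile.v_comp[seg.i_end - 1], 0.0, atol=1e-9)
            assert np.all(profile.v_zupt[~mask.moving] == 0)


class TestCalibration:
    def test_exact_line_recovers_factor(self):
        est = np.array([0.4, 1.0, 1.7, 2.5])
        pairs = np.column_stack([1.4735 * est, est])
        res = fit_calibration(pairs)
        assert res.factor == pytest.approx(1.4735)
        assert res.r2 == pytest.approx(1.0)

    def test_identity_when_estimates_true(self):
        est = np.array([0.5, 1.0, 2.0])
        res = fit_calibration(np.column_stack([est, est]))
        assert res.factor == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 0.0), (2.0, 0.0)])
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 1.0)])

    def test_parameter_recovery_on_generator(self):
        """40 defaulted walks recover the sensitivity deficit's reciprocal."""
        trials = walk_trials(40, seed=1, factor=1.0)
        res = fit_calibration(np.column_stack([trials["true"], trials["est_raw"]]))
        assert res.factor == pytest.approx(1.4735, abs=0.07)
        assert res.r2 >= 0.98
        val = validate_calibration(
            np.column_stack([trials["true"], trials["est_raw"]]), res.factor
        )
        assert val.factor == pytest.approx(1.0, abs=0.05)
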
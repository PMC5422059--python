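"""Navigation-mode kinematics: ZUPT, drift compensation, displacement.

Velocity is obtained by rectangular integration of the linear acceleration
at the 10 ms sampling time, with the acceleration pre-multiplied by the
moving mask (zero-velocity update: velocity is pinned to zero on every
static sample, so no error accumulates while the operator stands still).

Within each movement the integrated velocity still ends at a spurious
nonzero value.  That residual ("drift") is modeled as a straight line from
zero at the segment start to the observed final velocity and subtracted,
which forces the compensated velocity to end at exactly zero.  Compensated
velocities may dip below zero near the segment end; they are deliberately
not clamped — the systematic under-measurement this produces at walking
speed is absorbed by a single global calibration factor (default 1.4735)
estimated by through-origin regression of true against estimated
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from branchnav.motion_detect import MovementSegment, StaticMask
from branchnav.trace_io import ImuTrace

__all__ = [
    "KinematicProfile",
    "CalibrationResult",
    "integrate_velocity",
    "compensate_drift",
    "integrate_displacement",
    "fit_calibration",
    "validate_calibration",
    "compute_kinematics",
    "DEFAULT_CALIBRATION_FACTOR",
]

#: global displacement calibration factor for walking-speed movements
DEFAULT_CALIBRATION_FACTOR = 1.4735


@dataclass
class KinematicProfile:
    """Per-axis velocity and per-segment displacement of one NM trace.

    Velocity arrays are (n, 2) for the device X and Y axes; ``disp`` and
    ``disp_cal`` are (n_segments, 2) raw and calibrated displacements in
    meters; ``drift_line`` holds the per-segment, per-axis drift slopes in
    m/s^2.
    """

    v_raw: np.ndarray
    v_zupt: np.ndarray
    v_comp: np.ndarray
    drift_line: np.ndarray
    disp: np.ndarray
    disp_cal: np.ndarray
    segments: list
    factor: float


@dataclass
class CalibrationResult:
    """Through-origin regression of real on estimated displacement."""

    factor: float
    r2: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("calibration factor must be positive")


def integrate_velocity(trace: ImuTrace, mask: StaticMask, axes: tuple[int, ...] = (0, 1)) -> np.ndarray:
    """ZUPT velocity: cumulative a*dt with acceleration masked to movement.

    Static samples carry exactly zero velocity and each movement segment
    integrates from zero, so idle periods contribute no drift at all.
    Returns an (n, len(axes)) array.
    """
    n = len(trace)
    if mask.moving.size != n:
        raise ValueError("mask length does not match trace length")
    a = trace.acc[:, list(axes)] * mask.moving[:, None]
    v = np.cumsum(a, axis=0) * trace.dt
    # reset the running integral at each segment start, pin statics to 0
    for seg in mask.segments:
        v[seg.i_start:seg.i_end] -= v[seg.i_start] - a[seg.i_start] * trace.dt
    v[~mask.moving] = 0.0
    return v


def compensate_drift(v_zupt: np.ndarray, segment: MovementSegment, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the straight-line drift estimate inside one segment.

    The drift line runs from zero at the segment's first sample to the
    observed velocity at its last sample; after subtraction the compensated
    velocity at the final sample is exactly zero.  Returns ``(v_comp,
    slopes)`` where ``v_comp`` covers only the segment's samples.
    """
    if segment.n < 2:
        raise ValueError("drift compensation needs a segment of >= 2 samples")
    v = np.atleast_2d(np.asarray(v_zupt, dtype=float).T).T[segment.i_start:segment.i_end]
    elapsed = (segment.n - 1) * dt
    slopes = v[-1] / elapsed
    ramp = np.arange(segment.n)[:, None] * dt
    v_comp = v - slopes[None, :] * ramp
    return v_comp, slopes


def integrate_displacement(
    v_comp: np.ndarray, dt: float, factor: float = DEFAULT_CALIBRATION_FACTOR
) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular integral of compensated velocity over one segment.

    Returns ``(raw, calibrated)`` per-axis displacements in meters, the
    calibrated value being ``factor * raw``.
    """
    v = np.atleast_2d(np.asarray(v_comp, dtype=float).T).T
    raw = v.sum(axis=0) * dt
    return raw, factor * raw


def compute_kinematics(
    trace: ImuTrace,
    mask: StaticMask,
    factor: float = DEFAULT_CALIBRATION_FACTOR,
) -> KinematicProfile:
    """Full NM kinematic chain for one trace: ZUPT -> drift -> displacement."""
    n = len(trace)
    a_raw = trace.acc[:, :2]
    v_raw = np.cumsum(a_raw, axis=0) * trace.dt
    v_zupt = integrate_velocity(trace, mask)
    v_comp = v_zupt.copy()
    slopes = np.zeros((len(mask.segments), 2))
    disp = np.zeros((len(mask.segments), 2))
    for k, seg in enumerate(mask.segments):
        vc, m = compensate_drift(v_zupt, seg, trace.dt)
        v_comp[seg.i_start:seg.i_end] = vc
        slopes[k] = m
        disp[k], _ = integrate_displacement(vc, trace.dt, factor)
    return KinematicProfile(
        v_raw=v_raw,
        v_zupt=v_zupt,
        v_comp=v_comp,
        drift_line=slopes,
        disp=disp,
        disp_cal=factor * disp,
        segments=list(mask.segments),
        factor=factor,
    )


def fit_calibration(pairs) -> CalibrationResult:
    """Estimate the calibration factor from (real, estimated) displacements.

    Least-squares slope of real on estimated through the origin (the
    zero-intercept model is the validated one), with the uncentered
    coefficient of determination of that model.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need >= 2 (real, estimated) pairs")
    real, est = arr[:, 0], arr[:, 1]
    if np.allclose(est, 0):
        raise ValueError("estimated displacements are all zero; cannot calibrate")
    res = sm.OLS(real, est).fit()
    factor = float(res.params[0])
    return CalibrationResult(factor=factor, r2=float(res.rsquared), residuals=real - factor * est)


def validate_calibration(pairs, factor: float) -> CalibrationResult:
    """Re-regress real on factor-calibrated estimates; slope ~ 1 when the
    factor generalizes to held-out movements."""
    arr = np.asarray(pairs, dtype=float)
    calibrated = np.column_stack([arr[:, 0], factor * arr[:, 1]])
    return fit_calibration(calibrated)
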
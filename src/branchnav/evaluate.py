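"""Parameter-recovery experiments on the synthetic generators.

These are the evaluation harnesses behind ``branchnav evaluate`` and the
acceptance script: calibration-factor recovery and validation, calibrated
displacement accuracy, and boundary-detection rates for walks and scans.
Every experiment is a pure function of its seed.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from branchnav.acquisition import NoScanError, detect_scan_period
from branchnav.ins_nav import DEFAULT_CALIBRATION_FACTOR, compute_kinematics, fit_calibration, validate_calibration
from branchnav.motion_detect import DetectionConfig, build_mask
from branchnav.sharpness import compute_indexes, default_rois
from branchnav.synthgen import STEP_GRID, ScanSpec, WalkSpec, gen_branch_image, gen_scan_trace, gen_walk_trace

__all__ = [
    "walk_trials",
    "calibration_experiment",
    "displacement_mae",
    "scan_detection_rates",
    "pooled_detection_rate",
    "sharp_fixture_indexes",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds below 2**31 derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def walk_trials(
    n: int,
    seed: int,
    lengths: Sequence[float] = STEP_GRID,
    speed_range: tuple = (0.44, 0.44),
    factor: float = DEFAULT_CALIBRATION_FACTOR,
    cfg: Optional[DetectionConfig] = None,
):
    """Run n single-step walk traces through the calibrated NM pipeline.

    Step lengths cycle through ``lengths``; speeds are drawn uniformly from
    ``speed_range``.  Returns a dict of arrays: true length, raw and
    calibrated estimated length, detection success (exactly one segment,
    both boundaries within 0.5 s), and boundary errors.
    """
    cfg = cfg or DetectionConfig()
    seeds = _child_seeds(seed, n)
    rng = np.random.default_rng(seed)
    true_len = np.empty(n)
    est_raw = np.empty(n)
    est_cal = np.empty(n)
    detected = np.zeros(n, dtype=bool)
    start_err = np.full(n, np.nan)
    end_err = np.full(n, np.nan)
    for i in range(n):
        L = float(lengths[i % len(lengths)])
        speed = float(rng.uniform(*speed_range))
        spec = WalkSpec(step_lengths=[L], speed=speed, seed=int(seeds[i]))
        trace, truth = gen_walk_trace(spec)
        mask = build_mask(trace, cfg, mode="NM")
        profile = compute_kinematics(trace, mask, factor)
        net = profile.disp.sum(axis=0)
        true_len[i] = L
        est_raw[i] = float(np.hypot(*net))
        est_cal[i] = factor * est_raw[i]
        if len(mask.segments) == len(truth.segments) == 1:
            seg = mask.segments[0]
            t0, t1 = truth.segments[0]
            start_err[i] = seg.t_start - t0
            end_err[i] = seg.t_end - t1
            detected[i] = abs(start_err[i]) <= 0.5 and abs(end_err[i]) <= 0.5
    return {
        "true": true_len,
        "est_raw": est_raw,
        "est_cal": est_cal,
        "detected": detected,
        "start_err": start_err,
        "end_err": end_err,
    }


def calibration_experiment(
    n: int = 40,
    seed: int = 1,
    n_train: int = 25,
    speed: float = 0.44,
) -> dict:
    """Calibration-factor recovery with a train/validation split.

    Fits the through-origin factor on ``n_train`` movements (true against
    raw estimated displacement), then validates on the held-out movements
    by regressing true on factor-calibrated estimates — a slope near 1
    means the factor generalizes.
    """
    trials = walk_trials(n, seed, speed_range=(speed, speed), factor=1.0)
    pairs = np.column_stack([trials["true"], trials["est_raw"]])
    fit = fit_calibration(pairs[:n_train])
    val = validate_calibration(pairs[n_train:], fit.factor)
    return {
        "factor": fit.factor,
        "r2": fit.r2,
        "validation_slope": val.factor,
        "validation_r2": val.r2,
        "n_train": n_train,
        "n_val": n - n_train,
    }


def displacement_mae(
    n: int = 200,
    seed: int = 1,
    factor: float = DEFAULT_CALIBRATION_FACTOR,
    speed_range: tuple = (0.42, 0.45),
) -> dict:
    """Mean absolute error of calibrated displacements over n movements."""
    trials = walk_trials(n, seed, speed_range=speed_range, factor=factor)
    err = np.abs(trials["est_cal"] - trials["true"])
    return {"mae": float(err.mean()), "max_err": float(err.max()), "n": n}


def scan_detection_rates(n: int = 200, seed: int = 1, tol: float = 0.5) -> dict:
    """Start/end detection rates of the branch-scan detector, in percent."""
    seeds = _child_seeds(seed, n)
    start_ok = np.zeros(n, dtype=bool)
    end_ok = np.zeros(n, dtype=bool)
    for i in range(n):
        trace, truth = gen_scan_trace(ScanSpec(seed=int(seeds[i])))
        t0, t1 = truth.segments[0]
        try:
            period = detect_scan_period(trace)
        except NoScanError:
            continue
        start_ok[i] = abs(period.t_start - t0) <= tol
        end_ok[i] = abs(period.t_end - t1) <= tol
    return {
        "start_pct": 100.0 * start_ok.mean(),
        "end_pct": 100.0 * end_ok.mean(),
        "n": n,
    }


def pooled_detection_rate(n_walk: int = 100, n_scan: int = 100, seed: int = 1, tol: float = 0.5) -> dict:
    """Fraction of walks + scans whose movement period is labeled correctly.

    A case counts as correct when the mask yields exactly the true number
    of movement segments with both boundaries within ``tol`` seconds.
    """
    walk = walk_trials(n_walk, seed)
    ok = int(walk["detected"].sum())
    seeds = _child_seeds(seed + 1, n_scan)
    for i in range(n_scan):
        trace, truth = gen_scan_trace(ScanSpec(seed=int(seeds[i])))
        mask = build_mask(trace, mode="ACM")
        if len(mask.segments) != 1:
            continue
        seg = mask.segments[0]
        t0, t1 = truth.segments[0]
        if abs(seg.t_start - t0) <= tol and abs(seg.t_end - t1) <= tol:
            ok += 1
    total = n_walk + n_scan
    return {"pct": 100.0 * ok / total, "n": total}


def sharp_fixture_indexes(seed: int = 7, blur_sigma: float = 0.0) -> dict:
    """ROI sharpness indexes of the designated synthetic branch fixture."""
    frame, _ = gen_branch_image(seed=seed, blur_sigma=blur_sigma)
    h, w = frame.shape[:2]
    idx = compute_indexes(frame, default_rois(w, h))
    return {op: max(vals) for op, vals in idx.items()}
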
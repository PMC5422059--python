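"""Stage composition: end-to-end navigation and acquisition runs.

``run_navigation`` chains log reading, static-period detection, ZUPT/drift
kinematics and georeferencing into a track; ``run_acquisition`` chains
scan detection, video trimming and sharpness-based frame selection.  Both
write machine-readable outputs plus a run log (config hash, seed, version)
sufficient to reproduce deterministic stages bitwise.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from branchnav.acquisition import detect_scan_period, map_to_frames
from branchnav.config import AppConfig
from branchnav.georef import accumulate_track, track_to_geojson
from branchnav.ins_nav import compute_kinematics
from branchnav.motion_detect import build_mask
from branchnav.sharpness import FrameSelection, select_frames
from branchnav.trace_io import FrameSource, ImuTrace, read_trace, resample_uniform

__all__ = ["run_navigation", "run_acquisition", "error_budget", "segment_headings", "NavigationResult", "AcquisitionResult"]

#: calibrated INS mean relative error at walking speed, m
INS_RELATIVE_ERROR = 0.15


@dataclass
class NavigationResult:
    track: list
    profile: object
    mask: object
    summary: dict


@dataclass
class AcquisitionResult:
    period: object
    selection: FrameSelection
    manifest: dict


def segment_headings(trace: ImuTrace, mask) -> list[float]:
    """Circular mean of the yaw channel over each segment's moving samples."""
    out = []
    for seg in mask.segments:
        yaw = np.deg2rad(trace.orient[seg.i_start:seg.i_end, 0])
        mean = math.atan2(float(np.sin(yaw).mean()), float(np.cos(yaw).mean()))
        out.append(float(np.mod(math.degrees(mean), 360.0)))
    return out


def _write_run_log(out_dir: str, cfg: AppConfig, stage: str, extra: dict) -> None:
    from branchnav import __version__

    log = {"stage": stage, "config_digest": cfg.digest(), "config": cfg.to_dict(),
           "seed": cfg.seed, "version": __version__}
    log.update(extra)
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)


def run_navigation(
    log_path: str,
    config: Optional[AppConfig] = None,
    out_dir: Optional[str] = None,
    trace: Optional[ImuTrace] = None,
) -> NavigationResult:
    """Full navigation-mode chain: log -> mask -> kinematics -> track.

    A pre-built :class:`ImuTrace` may be passed instead of a path (the CLI
    always reads from disk).  Writes ``track.csv``, ``track.geojson`` and
    ``summary.json`` when ``out_dir`` is given.
    """
    cfg = config or AppConfig()
    try:
        if trace is None:
            trace = read_trace(log_path, mode="NM")
        if not trace.is_uniform():
            trace = resample_uniform(trace)
        mask = build_mask(trace, cfg.detection, mode="NM")
        profile = compute_kinematics(trace, mask, cfg.calibration_factor)
        headings = segment_headings(trace, mask)
        seed = trace.first_fix()
        movements = [
            (float(profile.disp_cal[k, 0]), float(profile.disp_cal[k, 1]), headings[k])
            for k in range(len(mask.segments))
        ]
        track = accumulate_track(seed, movements, cfg.projection, cfg.declination)
    except Exception as exc:
        raise type(exc)(f"[navigation] {exc}") from exc

    step_lengths = [float(np.hypot(dx, dy)) for dx, dy, _ in movements]
    summary = {
        "n_samples": len(trace),
        "n_segments": len(mask.segments),
        "n_track_points": len(track),
        "step_lengths_m": step_lengths,
        "total_distance_m": float(sum(step_lengths)),
        "warnings": [] if mask.segments else ["no movement detected; track is the seed point only"],
    }
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        pd.DataFrame(
            [
                {"segment_id": p.segment_id, "N": p.N, "E": p.E, "lat": p.lat,
                 "lon": p.lon, "source": p.source, "theta": p.theta}
                for p in track
            ]
        ).to_csv(os.path.join(out_dir, "track.csv"), index=False)
        with open(os.path.join(out_dir, "track.geojson"), "w") as fh:
            json.dump(track_to_geojson(track), fh)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        _write_run_log(out_dir, cfg, "navigation", {"log": log_path})
    return NavigationResult(track=track, profile=profile, mask=mask, summary=summary)


def run_acquisition(
    log_path: str,
    frames_dir: str,
    config: Optional[AppConfig] = None,
    out_dir: Optional[str] = None,
    trace: Optional[ImuTrace] = None,
    source: Optional[FrameSource] = None,
) -> AcquisitionResult:
    """Full acquisition chain: scan detection -> trim -> frame selection.

    The returned manifest carries the trim range, per-frame QC reports and
    the retained frame ids; ``selection.reacquire`` is True when all QC
    frames were blurred (exit code 2 at the CLI).
    """
    cfg = config or AppConfig()
    try:
        if trace is None:
            trace = read_trace(log_path, mode="ACM")
        if not trace.is_uniform():
            trace = resample_uniform(trace)
        if source is None:
            source = FrameSource.from_dir(frames_dir, fps=cfg.fps, t0_offset=cfg.t0_offset)
        period = detect_scan_period(trace, cfg.detection)
        frame_range = map_to_frames(period, source)
        selection = select_frames(
            source,
            frame_range=frame_range,
            thresholds=cfg.thresholds,
            operator=cfg.operator,
            retention=cfg.retention,
        )
    except Exception as exc:
        raise type(exc)(f"[acquisition] {exc}") from exc

    manifest = {
        "scan_t_start": period.t_start,
        "scan_t_end": period.t_end,
        "frame_start": frame_range[0],
        "frame_end": frame_range[1],
        "n_trimmed": frame_range[1] - frame_range[0],
        "n_selected": len(selection.selected),
        "selected": selection.selected,
        "reacquire": selection.reacquire,
        "warnings": period.warnings,
        "qc": [
            {"frame_id": r.frame_id, "accepted": r.accepted,
             "idx_sobel": r.idx_sobel, "idx_laplacian": r.idx_laplacian,
             "idx_canny": r.idx_canny}
            for r in selection.reports
        ],
    }
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "trim_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        rows = []
        for r in selection.reports:
            for roi, (s, l, c) in enumerate(zip(r.idx_sobel, r.idx_laplacian, r.idx_canny)):
                rows.append({"frame_id": r.frame_id, "roi": roi, "idx_sobel": s,
                             "idx_laplacian": l, "idx_canny": c, "accepted": r.accepted})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "sharpness.csv"), index=False)
        _write_run_log(out_dir, cfg, "acquisition", {"log": log_path, "frames": frames_dir})
    return AcquisitionResult(period=period, selection=selection, manifest=manifest)


def error_budget(config: Optional[AppConfig] = None, ins_relative_error: float = INS_RELATIVE_ERROR) -> float:
    """Worst-case georeferencing error: GPS seed error + INS relative error.

    The seed fix can be off by up to ``max_gps_error`` (m) and every INS
    point inherits that offset plus the dead-reckoning error itself.
    """
    cfg = config or AppConfig()
    if cfg.max_gps_error < 0 or ins_relative_error < 0:
        raise ValueError("error terms must be non-negative")
    return float(cfg.max_gps_error + ins_relative_error)
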
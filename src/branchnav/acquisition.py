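"""Acquisition-control mode: branch-scan detection and video trimming.

An ACM recording covers one branch scan: the handset is held still, moved
slowly along the branch, and held still again.  The Y-axis angular velocity
drives the static-period detector; the longest movement segment is the scan
(the acquisition protocol produces one scan per file, so shorter segments
are reported as warnings).  The scan period maps to video frame indexes
through the frame rate and the video/log start offset, and the mean scan
speed classifies into low (< 5 cm/s, sharp imagery), medium (5-10 cm/s)
and high (> 10 cm/s, motion blurred).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from branchnav.motion_detect import DetectionConfig, build_mask
from branchnav.trace_io import FrameSource, ImuTrace

__all__ = ["ScanPeriod", "NoScanError", "detect_scan_period", "map_to_frames", "classify_velocity"]


class NoScanError(ValueError):
    """No movement segment was found in an ACM trace."""


@dataclass
class ScanPeriod:
    """One detected branch-scan movement period.

    Times are on the sensor-log clock; frame indexes (filled by
    :func:`map_to_frames`) are half-open.  ``mean_speed`` in cm/s is
    optional external knowledge (the IMU cannot measure displacement at
    scan speeds below 5 cm/s, so it is never derived from acceleration).
    """

    t_start: float
    t_end: float
    frame_start: Optional[int] = None
    frame_end: Optional[int] = None
    velocity_class: Optional[str] = None
    mean_speed: Optional[float] = None
    warnings: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_scan_period(trace: ImuTrace, cfg: DetectionConfig | None = None) -> ScanPeriod:
    """Find the single branch-scan movement period in an ACM trace.

    Builds the gyro-Y static mask and returns the longest movement segment;
    any shorter segments become warnings.  Raises :class:`NoScanError`
    (re-acquire the branch) when nothing moved.
    """
    mask = build_mask(trace, cfg, mode="ACM")
    if not mask.segments:
        raise NoScanError(
            "no movement detected in the acquisition-control log; "
            "re-scan the branch"
        )
    best = max(mask.segments, key=lambda s: s.duration)
    warnings = [
        f"ignored spurious {s.duration:.2f} s segment at t={s.t_start:.2f} s"
        for s in mask.segments
        if s is not best
    ]
    period = ScanPeriod(t_start=best.t_start, t_end=best.t_end, warnings=warnings)
    return period


def map_to_frames(period: ScanPeriod, source: FrameSource) -> tuple[int, int]:
    """Map the scan period to a half-open video frame range.

    frame = round((t - t0_offset) * fps), clipped to the available frames.
    The clipped range is also written back onto ``period``.
    """
    n = len(source)
    f0 = round((period.t_start - source.t0_offset) * source.fps)
    f1 = round((period.t_end - source.t0_offset) * source.fps)
    f0c, f1c = max(0, min(f0, n)), max(0, min(f1, n))
    if f1c <= f0c:
        raise ValueError(
            f"scan period [{period.t_start:.2f}, {period.t_end:.2f}] s maps to "
            f"frames [{f0}, {f1}) which lies outside the {n}-frame video"
        )
    period.frame_start, period.frame_end = f0c, f1c
    return f0c, f1c


def classify_velocity(mean_speed: float) -> str:
    """Velocity class of a scan: low < 5 <= medium <= 10 < high, cm/s.

    The boundaries are inclusive into 'medium'.  Only low-speed scans give
    sharp frames.
    """
    if mean_speed < 0:
        raise ValueError("scan speed cannot be negative")
    if mean_speed < 5.0:
        return "low"
    if mean_speed <= 10.0:
        return "medium"
    return "high"
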
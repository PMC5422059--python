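"""Static/movement-period detection from inertial signal magnitudes.

The detector works per channel: the absolute magnitude of the inertial
signal is split into fixed blocks of ``M`` samples, every sample in a block
takes the block maximum (a piecewise-constant local-maxima envelope), and a
sample is labeled *moving* when that envelope exceeds a dynamic threshold

    THD = mean(Mag) + K * std(Mag),

floored at the channel's idle-noise ceiling ``min_thd`` (the largest
magnitude seen when the handset is held still).  Navigation mode uses the
X and Y linear accelerations (logical OR), acquisition-control mode uses the
Y-axis angular velocity alone.

Because the envelope is block-quantized (M = 85 samples is 0.85 s at
100 Hz), segment boundaries are refined inside the first and last block of
each detected run to the first/last raw-magnitude threshold crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from branchnav.trace_io import ImuTrace

__all__ = [
    "DetectionConfig",
    "MovementSegment",
    "StaticMask",
    "signal_magnitude",
    "local_max_envelope",
    "dynamic_threshold",
    "build_mask",
]

#: channels used per mode: name -> (attribute, column)
MODE_CHANNELS = {
    "NM": (("acc_x", ("acc", 0)), ("acc_y", ("acc", 1))),
    "ACM": (("gyro_y", ("gyro", 1)),),
}


@dataclass
class DetectionConfig:
    """Tunables of the static-period detector.

    Defaults are the field calibration for a hand-held handset at 100 Hz:
    window ``M`` = 85 samples; per-channel adjustment factors ``K`` and
    magnitude floors ``min_thd`` for the X/Y linear accelerations (m/s^2)
    and the Y angular velocity (rad/s).  ``min_segment`` debounces runs
    shorter than 0.3 s.  The dynamic threshold depends on the operator's
    hand; re-measure ``K``/``min_thd`` per operator rather than editing code.
    """

    M: int = 85
    K: dict = field(default_factory=lambda: {"acc_x": 1.8, "acc_y": 0.44, "gyro_y": 1.8})
    min_thd: dict = field(default_factory=lambda: {"acc_x": 0.15, "acc_y": 0.15, "gyro_y": 0.05})
    min_segment: float = 0.3

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if any(v < 0 for v in self.K.values()):
            raise ValueError("K factors must be >= 0")
        if any(v < 0 for v in self.min_thd.values()):
            raise ValueError("min_thd floors must be >= 0")


@dataclass(frozen=True)
class MovementSegment:
    """Maximal run of moving samples, half-open on indexes [i_start, i_end)."""

    i_start: int
    i_end: int
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n(self) -> int:
        return self.i_end - self.i_start


@dataclass
class StaticMask:
    """Per-sample movement labels plus the derived movement segments.

    ``moving`` is True during movement; multiplying the acceleration by it
    forces the signal to zero while the handset is idle, which is what kills
    the cumulative integration error.  ``thd_used`` records the threshold
    actually applied per channel.
    """

    moving: np.ndarray
    segments: list
    thd_used: dict

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=bool)

    @property
    def n_moving(self) -> int:
        return int(self.moving.sum())


def signal_magnitude(channel: np.ndarray) -> np.ndarray:
    """Element-wise magnitude sqrt(is^2) = |is| of one inertial signal."""
    return np.abs(np.asarray(channel, dtype=float))


def local_max_envelope(mag: np.ndarray, M: int) -> np.ndarray:
    """Piecewise-constant envelope: block maxima over fixed windows of M.

    Every sample in block [j, j+M) takes the block's maximum; the trailing
    partial block uses its own maximum.  Empty input yields empty output.
    """
    if M < 1:
        raise ValueError("window size M must be >= 1")
    mag = np.asarray(mag, dtype=float)
    n = mag.size
    if n == 0:
        return mag.copy()
    out = np.empty_like(mag)
    for j in range(0, n, M):
        out[j:j + M] = mag[j:j + M].max()
    return out


def dynamic_threshold(mag: np.ndarray, K: float, min_thd: float) -> float:
    """max(mean + K*std, min_thd) over the whole magnitude series.

    The standard deviation uses the population convention (denominator n).
    The floor is the idle-noise ceiling: with the handset held still the
    magnitude never exceeds it, so the detector cannot fire on hand tremor.
    """
    mag = np.asarray(mag, dtype=float)
    if mag.size == 0:
        raise ValueError("magnitude series is empty")
    return float(max(mag.mean() + K * mag.std(), min_thd))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True."""
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _refine_boundaries(
    moving: np.ndarray, mags: list[np.ndarray], thds: list[float], M: int
) -> np.ndarray:
    """Sharpen block-quantized run boundaries to raw threshold crossings.

    Within the first (last) block of each run the start (end) moves to the
    first (last) sample whose raw magnitude exceeds its channel threshold on
    any channel.  Only samples inside the run are relabeled, so refinement
    can shrink a run but never split or grow it.
    """
    exceeds = np.zeros_like(moving)
    for mag, thd in zip(mags, thds):
        exceeds |= mag > thd
    out = moving.copy()
    for i0, i1 in _runs(moving):
        head = exceeds[i0:min(i0 + M, i1)]
        hits = np.flatnonzero(head)
        if hits.size:
            out[i0:i0 + hits[0]] = False
        tail_lo = max(i1 - M, i0)
        tail = exceeds[tail_lo:i1]
        hits = np.flatnonzero(tail)
        if hits.size:
            out[tail_lo + hits[-1] + 1:i1] = False
    return out


def build_mask(trace: ImuTrace, cfg: DetectionConfig | None = None, mode: str | None = None) -> StaticMask:
    """Label every sample static/moving and extract movement segments.

    A sample is moving iff the local-max envelope exceeds the channel
    threshold on ANY of the mode's channels (NM: acc X, acc Y; ACM: gyro Y).
    Boundary blocks are refined to raw threshold crossings, then runs
    shorter than ``cfg.min_segment`` seconds are relabeled static.
    """
    cfg = cfg or DetectionConfig()
    mode = mode or trace.mode
    if mode not in MODE_CHANNELS:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(trace)
    moving = np.zeros(n, dtype=bool)
    thd_used: dict[str, float] = {}
    mags: list[np.ndarray] = []
    thds: list[float] = []
    for name, (attr, col) in MODE_CHANNELS[mode]:
        channel = getattr(trace, attr)[:, col]
        mag = signal_magnitude(channel)
        env = local_max_envelope(mag, cfg.M)
        thd = dynamic_threshold(mag, cfg.K[name], cfg.min_thd[name])
        thd_used[name] = thd
        moving |= env > thd
        mags.append(mag)
        thds.append(thd)

    moving = _refine_boundaries(moving, mags, thds, cfg.M)

    min_n = int(round(cfg.min_segment / trace.dt))
    for i0, i1 in _runs(moving):
        if i1 - i0 < min_n:
            moving[i0:i1] = False

    segments = [
        MovementSegment(i0, i1, float(trace.t[i0]), float(trace.t[i1 - 1]) + trace.dt)
        for i0, i1 in _runs(moving)
    ]
    return StaticMask(moving=moving, segments=segments, thd_used=thd_used)
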
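"""Synthetic IMU traces and branch-like images with ground truth.

The generators emulate the three kinds of field data the pipeline consumes,
so every stage can be exercised and scored without field recordings:

* **Walk traces (NM)** — hand-carried steps of 0.5-3.75 m at ~0.44 m/s.
  Each step follows a trapezoidal velocity profile (20 % ramps).  The
  accelerometer sees the true step acceleration scaled by a sensitivity
  deficit (default 1/1.4735 — the systematic under-measurement a global
  calibration factor later undoes), plus speed-proportional gait vibration,
  a zero-integral heel-strike jolt at step start and end, white sensor
  noise, and a constant per-trace bias of up to +-1 mg.  Idle gaps carry
  bounded noise (+-10 mg), below the detector's magnitude floor.

* **Scan traces (ACM)** — a single low-speed branch scan: the Y gyro shows
  hand tremor plus repeated micro-adjustment impulses while the handset
  moves along the branch (pick-up and set-down transients bound the scan),
  and only a small noise floor while idle.

* **Branch images** — red-dominant fruit ellipses and green leaf blobs on
  a speckled branch/soil background spanning the central band, so all
  three default ROIs contain structure.  Defocus (Gaussian) and horizontal
  motion blur emulate too-fast scans.

All generators are pure functions of their spec (bitwise reproducible per
seed), and each returns a :class:`GroundTruth` carrying the quantities the
pipeline is later scored against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter1d

from branchnav.trace_io import NOMINAL_DT, ImuTrace

__all__ = [
    "WalkSpec",
    "ScanSpec",
    "GroundTruth",
    "gen_walk_trace",
    "gen_scan_trace",
    "gen_branch_image",
    "truth_mask",
]

#: default step grid, m (the calibration-course point spacings)
STEP_GRID = (0.5, 0.75, 1.0, 1.5, 2.25, 3.0, 3.75)


@dataclass
class WalkSpec:
    """Conditions of one synthetic navigation-mode walk.

    ``noise_idle`` is the +-bound of the idle accelerometer reading in
    m/s^2 (default 0.098 = 10 mg); ``accel_sensitivity`` scales the true
    step acceleration into the measured one (default 1/1.4735).
    ``headings`` are geographic bearings per step (deg); the logged yaw is
    the magnetic azimuth heading + declination.
    """

    step_lengths: Sequence[float] = STEP_GRID
    speed: float = 0.44                       # m/s along the step
    headings: Optional[Sequence[float]] = None  # deg, default all 0 (north)
    idle_gap: float = 2.0                     # s of stillness around steps
    noise_idle: float = 0.098                 # m/s^2 bound (+-10 mg)
    accel_sensitivity: float = 1.0 / 1.4735
    bias_bound: float = 0.0098                # m/s^2 (+-1 mg) per-trace bias
    gait_amp: float = 0.8                     # m/s^2 vibration at full speed
    gait_freq: float = 2.0                    # Hz (step cadence)
    sway_amp: float = 0.3                     # m/s^2 lateral vibration
    jolt_amp: float = 0.6                     # m/s^2 heel-strike transient
    noise_move: float = 0.02                  # m/s^2 white noise while moving
    declination: float = -6.13                # deg, yaw = heading + declination
    start: tuple = (4.99, -75.60)             # seed (lat, lon), WGS84
    max_gps_error: float = 0.0                # m, uniform seed perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.step_lengths):
            raise ValueError("step lengths must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.accel_sensitivity <= 0:
            raise ValueError("sensitivity must be positive")


@dataclass
class ScanSpec:
    """Conditions of one synthetic acquisition-control branch scan."""

    duration: float = 15.0          # s of movement along the branch
    speed_class: str = "low"        # low | medium | high
    gyro_noise: float = 0.01        # rad/s idle noise sigma
    lead: tuple = (1.5, 2.5)        # s of idle before the scan (range)
    tail: float = 3.0               # s of idle after
    tremor_amp: float = 0.1         # rad/s continuous hand tremor
    tremor_freq: float = 9.0        # Hz
    impulse_amp: tuple = (0.4, 0.7)  # rad/s micro-adjustment peaks
    impulse_gap: tuple = (0.35, 0.65)  # s between impulses
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("scan duration must be positive")
        if self.speed_class not in ("low", "medium", "high"):
            raise ValueError("speed_class must be low, medium or high")


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring the pipeline.

    ``segments`` are true movement windows (t_start, t_end) in seconds;
    ``step_disp`` are true per-step (dX, dY) device-frame displacements in
    meters; ``headings`` geographic bearings per step; ``track`` the true
    cumulative (dN, dE) plane offsets from the seed; ``blur_sigma`` /
    ``motion_blur_len`` describe image degradation; ``mean_speed`` in cm/s
    for scans.
    """

    segments: list = field(default_factory=list)
    step_disp: list = field(default_factory=list)
    headings: list = field(default_factory=list)
    track: list = field(default_factory=list)
    seed_error: float = 0.0
    blur_sigma: float = 0.0
    motion_blur_len: int = 0
    mean_speed: float = float("nan")


def truth_mask(trace: ImuTrace, truth: GroundTruth):
    """Oracle static mask built from the generator's true segments.

    Lets the integration chain be tested in isolation from the detector
    (e.g. on vibration-free traces whose cruise phase carries no
    acceleration signature at all).
    """
    from branchnav.motion_detect import MovementSegment, StaticMask

    moving = np.zeros(len(trace), dtype=bool)
    segments = []
    for t0, t1 in truth.segments:
        i0 = int(round(t0 / trace.dt))
        i1 = int(round(t1 / trace.dt))
        moving[i0:i1] = True
        segments.append(MovementSegment(i0, i1, t0, t1))
    return StaticMask(moving=moving, segments=segments, thd_used={})


def _trapezoid_profile(L: float, speed: float, dt: float, ramp_frac: float = 0.2):
    """Per-sample (accel, velocity) of a trapezoidal-velocity step.

    The velocity is sampled on the grid and rescaled so its rectangular
    integral is exactly ``L``; acceleration is its backward difference.
    Cumulative rectangular integration therefore reproduces the velocity
    and the displacement to machine precision — the sampled profile IS the
    ground truth, free of quadrature bias.  Mean speed equals ``speed``.
    """
    T = L / speed
    n = max(int(round(T / dt)), 4)
    t = (np.arange(n) + 1) * dt
    T = n * dt
    Tr = ramp_frac * T
    v_peak = L / (T - Tr)
    vel = np.where(
        t < Tr, v_peak * t / Tr,
        np.where(t > T - Tr, v_peak * (T - t) / Tr, v_peak),
    )
    vel = vel * (L / (vel.sum() * dt))
    acc = np.diff(vel, prepend=0.0) / dt
    return acc, vel, float(vel.max())


def _bounded_noise(rng: np.random.Generator, n: int, bound: float) -> np.ndarray:
    """Gaussian noise with sigma = bound/3, clipped to +-bound."""
    return np.clip(rng.normal(0.0, bound / 3.0, n), -bound, bound)


def _biphasic_jolt(n_w: int, amp: float) -> np.ndarray:
    """One full sine period: a sharp transient whose integral is exactly 0."""
    return amp * np.sin(2 * np.pi * np.arange(n_w) / n_w)


def gen_walk_trace(spec: WalkSpec) -> tuple[ImuTrace, GroundTruth]:
    """Synthesize one NM walk and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    dt = NOMINAL_DT
    headings = list(spec.headings) if spec.headings is not None else [0.0] * len(spec.step_lengths)
    if len(headings) != len(spec.step_lengths):
        raise ValueError("headings and step_lengths must have equal length")

    n_idle = int(round(spec.idle_gap / dt))
    acc_y_parts, acc_x_parts = [], []
    yaw_parts = []
    truth = GroundTruth()
    t_cursor = 0.0

    def idle_block(n: int):
        acc_y_parts.append(_bounded_noise(rng, n, spec.noise_idle))
        acc_x_parts.append(_bounded_noise(rng, n, spec.noise_idle))
        yaw_parts.append(np.full(n, np.nan))  # filled with last heading later

    idle_block(n_idle)
    t_cursor += n_idle * dt
    N_true = E_true = 0.0
    for L, hdg in zip(spec.step_lengths, headings):
        step_a, step_v, v_peak = _trapezoid_profile(L, spec.speed, dt)
        n_s = step_a.size
        phase = rng.uniform(0, 2 * np.pi)
        rel = step_v / v_peak
        tt = np.arange(n_s) * dt
        vib_y = spec.gait_amp * rel * np.cos(2 * np.pi * spec.gait_freq * tt + phase)
        vib_x = spec.sway_amp * rel * np.cos(2 * np.pi * spec.gait_freq * 0.5 * tt + rng.uniform(0, 2 * np.pi))
        ay = spec.accel_sensitivity * step_a + vib_y + rng.normal(0, spec.noise_move, n_s)
        ax = vib_x + rng.normal(0, spec.noise_move, n_s)
        n_w = max(int(round(0.06 / dt)), 2)
        jolt = _biphasic_jolt(n_w, spec.jolt_amp)
        ay[:n_w] += jolt
        ay[-n_w:] += jolt
        acc_y_parts.append(ay)
        acc_x_parts.append(ax)
        yaw_parts.append(np.full(n_s, hdg + spec.declination) + rng.normal(0, 1.0, n_s))
        truth.segments.append((t_cursor, t_cursor + n_s * dt))
        truth.step_disp.append((0.0, L))
        truth.headings.append(hdg)
        N_true += L * math.cos(math.radians(hdg))
        E_true += L * math.sin(math.radians(hdg))
        truth.track.append((N_true, E_true))
        t_cursor += n_s * dt
        idle_block(n_idle)
        t_cursor += n_idle * dt

    acc_y = np.concatenate(acc_y_parts)
    acc_x = np.concatenate(acc_x_parts)
    n = acc_y.size
    bias = rng.uniform(-spec.bias_bound, spec.bias_bound, 2)
    acc_x = acc_x + bias[0]
    acc_y = acc_y + bias[1]

    yaw = np.concatenate(yaw_parts)
    # hold the most recent heading through idle gaps (handset keeps pointing)
    last = headings[0] + spec.declination if headings else 0.0
    for i in range(n):
        if math.isnan(yaw[i]):
            yaw[i] = last + rng.normal(0, 1.0)
        else:
            last = yaw[i]
    yaw = np.mod(yaw, 360.0)

    t = dt * np.arange(n)
    gps_lat = np.full(n, np.nan)
    gps_lon = np.full(n, np.nan)
    lat0, lon0 = spec.start
    if spec.max_gps_error > 0:
        r = rng.uniform(0, spec.max_gps_error)
        ang = rng.uniform(0, 2 * np.pi)
        # small-offset conversion: meters -> degrees at the seed latitude
        lat0 = lat0 + (r * math.cos(ang)) / 111320.0
        lon0 = lon0 + (r * math.sin(ang)) / (111320.0 * math.cos(math.radians(lat0)))
        truth.seed_error = r
    gps_lat[0], gps_lon[0] = lat0, lon0

    trace = ImuTrace(
        t=t,
        acc=np.column_stack([acc_x, acc_y, _bounded_noise(rng, n, spec.noise_idle)]),
        gyro=rng.normal(0, 0.01, (n, 3)),
        orient=np.column_stack([yaw, rng.normal(0, 1.0, n), rng.normal(0, 1.0, n)]),
        mag=rng.normal(25.0, 0.5, (n, 3)),
        gps_lat=gps_lat,
        gps_lon=gps_lon,
        dt=dt,
        mode="NM",
        label=f"walk-seed{spec.seed}",
    )
    return trace, truth


_SCAN_SPEEDS = {"low": 3.0, "medium": 7.5, "high": 12.0}  # cm/s


def gen_scan_trace(spec: ScanSpec) -> tuple[ImuTrace, GroundTruth]:
    """Synthesize one ACM branch scan and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    dt = NOMINAL_DT
    lead = rng.uniform(*spec.lead)
    n_lead = int(round(lead / dt))
    n_scan = int(round(spec.duration / dt))
    n_tail = int(round(spec.tail / dt))
    n = n_lead + n_scan + n_tail

    gyro_y = rng.normal(0, spec.gyro_noise, n)
    tt = np.arange(n_scan) * dt
    tremor = spec.tremor_amp * np.sin(2 * np.pi * spec.tremor_freq * tt + rng.uniform(0, 2 * np.pi))
    seg = tremor + rng.normal(0, 0.03, n_scan)

    # micro-adjustment impulses; pick-up / set-down transients bound the scan
    n_w = max(int(round(0.04 / dt)), 2)
    centers = [0.03]
    t_next = 0.03 + rng.uniform(*spec.impulse_gap)
    while t_next < spec.duration - 0.15:
        centers.append(t_next)
        t_next += rng.uniform(*spec.impulse_gap)
    centers.append(spec.duration - 0.03)
    for tc in centers:
        amp = rng.uniform(*spec.impulse_amp) * rng.choice([-1.0, 1.0])
        ic = int(round(tc / dt))
        lo, hi = max(0, ic - n_w), min(n_scan, ic + n_w + 1)
        window = np.arange(lo, hi) - ic
        seg[lo:hi] += amp * np.exp(-0.5 * (window * dt / 0.012) ** 2)

    gyro_y[n_lead:n_lead + n_scan] += seg

    t = dt * np.arange(n)
    trace = ImuTrace(
        t=t,
        acc=np.column_stack([
            _bounded_noise(rng, n, 0.098),
            _bounded_noise(rng, n, 0.098),
            _bounded_noise(rng, n, 0.098),
        ]),
        gyro=np.column_stack([rng.normal(0, spec.gyro_noise, n), gyro_y, rng.normal(0, spec.gyro_noise, n)]),
        orient=np.column_stack([
            np.mod(90.0 + rng.normal(0, 1.0, n), 360.0),
            rng.normal(0, 1.0, n),
            rng.normal(0, 1.0, n),
        ]),
        mag=rng.normal(25.0, 0.5, (n, 3)),
        gps_lat=np.full(n, np.nan),
        gps_lon=np.full(n, np.nan),
        dt=dt,
        mode="ACM",
        label=f"scan-seed{spec.seed}",
    )
    truth = GroundTruth(
        segments=[(n_lead * dt, (n_lead + n_scan) * dt)],
        mean_speed=_SCAN_SPEEDS[spec.speed_class],
    )
    return trace, truth


def gen_branch_image(
    seed: int,
    blur_sigma: float = 0.0,
    motion_blur_len: int = 0,
    size: tuple = (1080, 1920),
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize one branch-like RGB frame (uint8) and its ground truth.

    Red-dominant fruit ellipses and green leaf blobs sit on a speckled
    branch running through the central horizontal band, so the three
    default ROIs all contain high-frequency structure.  ``blur_sigma``
    applies Gaussian defocus, ``motion_blur_len`` a horizontal box blur
    (pixels), emulating scans faster than 5 cm/s.
    """
    if blur_sigma < 0 or motion_blur_len < 0:
        raise ValueError("blur parameters must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]

    img = np.zeros((h, w, 3), float)
    img[..., 0] = 95.0
    img[..., 1] = 80.0
    img[..., 2] = 60.0
    # low-frequency illumination field
    img += 25.0 * np.sin(2 * np.pi * xx / (w / rng.uniform(1.5, 3.5)))[..., None] * 0.4
    # soil/foliage speckle
    img += rng.uniform(-25, 25, (h, w, 1))

    # the branch: a woody strip through the central band with coarse bark texture
    y_c = h / 2 + rng.uniform(-10, 10)
    half = h * 0.09
    band = np.abs(yy - y_c) < half
    bark = rng.uniform(-75, 75, (h, w))
    img[..., 0][band] = 125.0 + bark[band]
    img[..., 1][band] = 95.0 + 0.8 * bark[band]
    img[..., 2][band] = 70.0 + 0.6 * bark[band]

    # leaves: green elliptic blobs off the band
    for _ in range(14):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        rx, ry = rng.uniform(60, 140), rng.uniform(40, 90)
        blob = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        img[..., 1][blob] = 140.0 + rng.uniform(-30, 30) + 0.5 * bark[blob]
        img[..., 0][blob] = 70.0 + 0.4 * bark[blob]

    # fruits: red ellipses clustered on the central band, with glossy texture
    n_fruit = 26
    for k in range(n_fruit):
        cx = (k + rng.uniform(0.1, 0.9)) * w / n_fruit
        cy = y_c + rng.uniform(-half, half)
        r = rng.uniform(26, 46)
        fruit = ((xx - cx) / r) ** 2 + ((yy - cy) / (0.85 * r)) ** 2 <= 1.0
        img[..., 0][fruit] = 205.0 + rng.uniform(-15, 15) + rng.uniform(-65, 65, int(fruit.sum()))
        img[..., 1][fruit] = 55.0 + 0.3 * bark[fruit]
        img[..., 2][fruit] = 45.0 + 0.3 * bark[fruit]

    if motion_blur_len > 1:
        img = uniform_filter1d(img, size=int(motion_blur_len), axis=1, mode="nearest")
    if blur_sigma > 0:
        img = gaussian_filter(img, sigma=(blur_sigma, blur_sigma, 0), mode="nearest")

    out = np.clip(img, 0, 255).astype(np.uint8)
    truth = GroundTruth(blur_sigma=blur_sigma, motion_blur_len=motion_blur_len)
    return out, truth
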
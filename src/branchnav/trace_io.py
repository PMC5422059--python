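"""Sensor-log dialect and frame sources.

A recording is a single CSV file with one header line and the columns

    t, accX, accY, accZ, gyroX, gyroY, gyroZ, yaw, pitch, roll,
    magX, magY, magZ, lat, lon

``t`` is seconds from recording start (nominal 100 Hz, 10 ms spacing),
acceleration is gravity-removed linear acceleration in m/s^2 on the device
axes (X across the short screen edge, Y along the long edge, Z out of the
screen), angular velocity is rad/s, orientation angles are degrees with yaw
measured clockwise from magnetic north in [0, 360), magnetometer in uT, and
``lat``/``lon`` are WGS84 decimal degrees, left blank on rows without a GPS
fix.  Navigation-mode (NM) recordings must carry at least one fix; the
acquisition-control mode (ACM) needs none.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImuSample",
    "ImuTrace",
    "FrameSource",
    "TraceError",
    "TraceParseError",
    "EmptyTraceError",
    "read_trace",
    "write_trace",
    "resample_uniform",
    "COLUMNS",
]

COLUMNS = (
    "t",
    "accX", "accY", "accZ",
    "gyroX", "gyroY", "gyroZ",
    "yaw", "pitch", "roll",
    "magX", "magY", "magZ",
    "lat", "lon",
)

NOMINAL_DT = 0.01


class TraceError(ValueError):
    """Base class for sensor-log problems."""


class TraceParseError(TraceError):
    """A malformed row; carries the 1-based line number of the offender."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyTraceError(TraceError):
    """The log holds no samples."""


@dataclass(frozen=True)
class ImuSample:
    """One 100 Hz sensor row.

    ``gps`` is ``None`` on rows where no fix arrived, else ``(lat, lon)``
    in WGS84 decimal degrees.
    """

    t: float
    acc_lin: tuple[float, float, float]
    gyro: tuple[float, float, float]
    orient: tuple[float, float, float]  # yaw, pitch, roll, degrees
    mag: tuple[float, float, float]
    gps: Optional[tuple[float, float]] = None


@dataclass
class ImuTrace:
    """Uniformly sampled multi-channel sensor record.

    Channels are stored as column arrays of equal length; ``gps_lat`` /
    ``gps_lon`` hold NaN on rows without a fix.  Iterating the trace yields
    :class:`ImuSample` views.
    """

    t: np.ndarray
    acc: np.ndarray      # (n, 3) m/s^2
    gyro: np.ndarray     # (n, 3) rad/s
    orient: np.ndarray   # (n, 3) yaw/pitch/roll, degrees
    mag: np.ndarray      # (n, 3) uT
    gps_lat: np.ndarray  # (n,) degrees, NaN = no fix
    gps_lon: np.ndarray
    dt: float = NOMINAL_DT
    mode: str = "NM"
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.size
        self.acc = np.asarray(self.acc, dtype=float).reshape(n, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(n, 3)
        self.orient = np.asarray(self.orient, dtype=float).reshape(n, 3)
        self.mag = np.asarray(self.mag, dtype=float).reshape(n, 3)
        self.gps_lat = np.asarray(self.gps_lat, dtype=float).reshape(n)
        self.gps_lon = np.asarray(self.gps_lon, dtype=float).reshape(n)
        if self.mode not in ("NM", "ACM"):
            raise TraceError(f"unknown mode {self.mode!r}; expected 'NM' or 'ACM'")
        if n and np.any(np.diff(self.t) <= 0):
            raise TraceError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def __iter__(self) -> Iterator[ImuSample]:
        for i in range(len(self)):
            yield self.sample(i)

    def sample(self, i: int) -> ImuSample:
        gps = None
        if not math.isnan(self.gps_lat[i]):
            gps = (float(self.gps_lat[i]), float(self.gps_lon[i]))
        return ImuSample(
            t=float(self.t[i]),
            acc_lin=tuple(self.acc[i]),
            gyro=tuple(self.gyro[i]),
            orient=tuple(self.orient[i]),
            mag=tuple(self.mag[i]),
            gps=gps,
        )

    @property
    def n_fixes(self) -> int:
        return int(np.sum(~np.isnan(self.gps_lat)))

    def first_fix(self) -> tuple[float, float]:
        """(lat, lon) of the earliest GPS fix."""
        idx = np.flatnonzero(~np.isnan(self.gps_lat))
        if idx.size == 0:
            raise TraceError(
                "trace has no GPS fix; provide a manual seed position or "
                "re-record with GPS enabled"
            )
        i = idx[0]
        return float(self.gps_lat[i]), float(self.gps_lon[i])

    def is_uniform(self, rtol: float = 0.5) -> bool:
        if len(self) < 2:
            return True
        d = np.diff(self.t)
        return bool(np.all(np.abs(d - self.dt) <= rtol * self.dt))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "accX": self.acc[:, 0], "accY": self.acc[:, 1], "accZ": self.acc[:, 2],
                "gyroX": self.gyro[:, 0], "gyroY": self.gyro[:, 1], "gyroZ": self.gyro[:, 2],
                "yaw": self.orient[:, 0], "pitch": self.orient[:, 1], "roll": self.orient[:, 2],
                "magX": self.mag[:, 0], "magY": self.mag[:, 1], "magZ": self.mag[:, 2],
                "lat": self.gps_lat, "lon": self.gps_lon,
            }
        )
        return df


@dataclass
class FrameSource:
    """Ordered video frames plus the timing needed to map log time to frames.

    ``frames`` are opaque handles (file paths or arrays); ``t0_offset`` is the
    time of frame 0 on the sensor-log clock (0 when the same button press
    starts both the video and the log).
    """

    frames: Sequence
    fps: float = 30.0
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.frames) < 1:
            raise ValueError("frame source holds no frames")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_dir(cls, path: str, fps: float = 30.0, t0_offset: float = 0.0) -> "FrameSource":
        """Frames as a lexicographically sorted directory of PNG/JPEG files."""
        if not os.path.isdir(path):
            raise IOError(f"frame directory not found: {path}")
        exts = (".png", ".jpg", ".jpeg")
        files = sorted(
            os.path.join(path, f)
            for f in os.listdir(path)
            if f.lower().endswith(exts)
        )
        if not files:
            raise IOError(f"no PNG/JPEG frames in {path}")
        return cls(frames=files, fps=fps, t0_offset=t0_offset)


def read_trace(path: str, mode: str = "NM") -> ImuTrace:
    """Read a sensor log CSV into an :class:`ImuTrace`.

    Raises :class:`TraceParseError` (with the offending line number) on
    malformed rows, :class:`EmptyTraceError` on a header-only or empty file,
    and :class:`TraceError` when timestamps are non-monotone or an NM log
    carries no GPS fix.
    """
    if not os.path.exists(path):
        raise IOError(f"sensor log not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyTraceError(f"{path}: file is empty") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: header is missing columns {missing}", line=1)
    if len(df) == 0:
        raise EmptyTraceError(f"{path}: no samples after the header")

    def col(name: str, required: bool) -> np.ndarray:
        raw = df[name]
        vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        bad = np.isnan(vals) & raw.notna().to_numpy()
        if required:
            bad |= raw.isna().to_numpy()
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise TraceParseError(
                f"column {name!r} has a malformed value {raw.iloc[i]!r}",
                line=i + 2,  # header is line 1
            )
        return vals

    t = col("t", required=True)
    data = {name: col(name, required=True) for name in COLUMNS[1:13]}
    lat = col("lat", required=False)
    lon = col("lon", required=False)
    if np.any(np.isnan(lat) != np.isnan(lon)):
        i = int(np.flatnonzero(np.isnan(lat) != np.isnan(lon))[0])
        raise TraceParseError("lat/lon must be blank or present together", line=i + 2)

    if np.any(np.diff(t) <= 0):
        i = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise TraceParseError("timestamps are not strictly increasing", line=i + 3)

    dt = float(np.median(np.diff(t))) if t.size > 1 else NOMINAL_DT
    trace = ImuTrace(
        t=t,
        acc=np.column_stack([data["accX"], data["accY"], data["accZ"]]),
        gyro=np.column_stack([data["gyroX"], data["gyroY"], data["gyroZ"]]),
        orient=np.column_stack([data["yaw"], data["pitch"], data["roll"]]),
        mag=np.column_stack([data["magX"], data["magY"], data["magZ"]]),
        gps_lat=lat,
        gps_lon=lon,
        dt=dt,
        mode=mode,
        label=os.path.splitext(os.path.basename(path))[0],
    )
    if mode == "NM" and trace.n_fixes == 0:
        raise TraceError(
            f"{path}: navigation-mode log holds no GPS fix; a seed position is required"
        )
    return trace


def write_trace(trace: ImuTrace, path: str) -> None:
    """Write the CSV dialect; ``read_trace(write_trace(x))`` is the identity.

    Values are written at full double precision, GPS columns are blank where
    no fix exists.
    """
    df = trace.to_dataframe()
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")


def _interp_angle(tq: np.ndarray, t: np.ndarray, ang_deg: np.ndarray, wrap: bool) -> np.ndarray:
    """Linear interpolation on the circle (shortest angular path), degrees.

    With ``wrap`` the result is folded into [0, 360) (yaw); otherwise the
    interpolated values stay on the original branch (pitch/roll).
    """
    rad = np.deg2rad(ang_deg)
    unwrapped = np.unwrap(rad)
    out = np.rad2deg(np.interp(tq, t, unwrapped))
    return np.mod(out, 360.0) if wrap else out


def resample_uniform(trace: ImuTrace, dt: float = NOMINAL_DT) -> ImuTrace:
    """Resample a (possibly jittered) trace onto a uniform grid.

    Continuous channels are interpolated linearly, orientation angles on the
    circle, and GPS fixes are snapped to the nearest grid sample.  First and
    last timestamps are preserved; the call is idempotent on already-uniform
    input.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(trace) < 2:
        raise TraceError("resampling needs at least 2 samples")
    t = trace.t
    n_out = int(round((t[-1] - t[0]) / dt)) + 1
    tq = t[0] + dt * np.arange(n_out)
    tq[-1] = t[-1]  # guard against rounding past the final sample

    def lin(col: np.ndarray) -> np.ndarray:
        return np.interp(tq, t, col)

    acc = np.column_stack([lin(trace.acc[:, k]) for k in range(3)])
    gyro = np.column_stack([lin(trace.gyro[:, k]) for k in range(3)])
    mag = np.column_stack([lin(trace.mag[:, k]) for k in range(3)])
    orient = np.column_stack(
        [_interp_angle(tq, t, trace.orient[:, k], wrap=(k == 0)) for k in range(3)]
    )

    lat = np.full(n_out, np.nan)
    lon = np.full(n_out, np.nan)
    fix_idx = np.flatnonzero(~np.isnan(trace.gps_lat))
    for i in fix_idx:
        j = int(np.argmin(np.abs(tq - t[i])))
        lat[j] = trace.gps_lat[i]
        lon[j] = trace.gps_lon[i]

    return ImuTrace(
        t=tq, acc=acc, gyro=gyro, orient=orient, mag=mag,
        gps_lat=lat, gps_lon=lon, dt=dt, mode=trace.mode, label=trace.label,
    )
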
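"""Georeferencing: Gauss-Krüger plane coordinates and track accumulation.

Metric displacements from the INS are accumulated in transverse-Mercator
plane coordinates (Northing, Easting at scale factor 1 — Gauss-Krüger) and
converted back to WGS84 latitude/longitude for mapping.  The projection is
implemented with the Krüger series in the third flattening (terms through
n^4, sub-millimeter over a projection zone), both forward and inverse.

Headings come from the handset azimuth, which references magnetic north;
subtracting the site's magnetic declination (default -6.13 deg) yields the
geographic heading theta, and a per-movement displacement (dX across the
device, dY along it) maps into the plane as

    dN = dY*cos(theta) + dX*cos(theta + 90)
    dE = dY*sin(theta) + dX*sin(theta + 90)

with trigonometry in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ProjectionSpec",
    "TrackPoint",
    "heading_correction",
    "displacement_to_plane",
    "wgs84_to_plane",
    "plane_to_wgs84",
    "accumulate_track",
    "DEFAULT_DECLINATION",
]

#: site magnetic declination, degrees (negative = magnetic north east of true)
DEFAULT_DECLINATION = -6.13


@dataclass(frozen=True)
class ProjectionSpec:
    """Transverse-Mercator (Gauss-Krüger) zone parameters.

    Defaults are the MAGNA-SIRGAS Bogotá zone (GRS80 ellipsoid, origin
    4.5962 N 74.0775 W, false origin 1 000 000 / 1 000 000 m), which covers
    the central Colombian coffee region.  Any zone can be configured; all
    plane coordinates in a run must use the same spec.
    """

    a: float = 6378137.0                      # semi-major axis, m
    f: float = 1.0 / 298.257222101            # flattening
    lat0: float = 4.596200416666666           # latitude of origin, deg
    lon0: float = -74.07750791666666          # central meridian, deg
    false_northing: float = 1000000.0
    false_easting: float = 1000000.0
    k0: float = 1.0                           # Gauss-Krüger scale factor

    def __post_init__(self) -> None:
        if not (0.0 < self.f < 1.0 / 290.0):
            raise ValueError("flattening outside the plausible ellipsoid range")
        for v in (self.a, self.lat0, self.lon0, self.false_northing, self.false_easting, self.k0):
            if not math.isfinite(v):
                raise ValueError("projection parameters must be finite")


@dataclass(frozen=True)
class TrackPoint:
    """Georeferenced position in plane and ellipsoidal coordinates.

    ``source`` records provenance: 'GPS' for the seed fix, 'INS' for dead-
    reckoned points.  ``theta`` is the geographic heading (deg) used for the
    step into this point (NaN for the seed).
    """

    N: float
    E: float
    lat: float
    lon: float
    source: str
    segment_id: int
    theta: float = float("nan")


def heading_correction(azimuth: float, declination: float = DEFAULT_DECLINATION) -> float:
    """Geographic heading theta = azimuth - declination, wrapped to [0, 360)."""
    return float(np.mod(azimuth - declination, 360.0))


def displacement_to_plane(dX: float, dY: float, theta: float) -> tuple[float, float]:
    """Rotate a device-frame displacement into (dN, dE), degrees trig."""
    th = math.radians(theta)
    th90 = math.radians(theta + 90.0)
    dN = dY * math.cos(th) + dX * math.cos(th90)
    dE = dY * math.sin(th) + dX * math.sin(th90)
    return dN, dE


# --- Krüger series machinery -------------------------------------------------

def _series_coeffs(n: float) -> tuple[np.ndarray, np.ndarray]:
    alpha = np.array([
        n / 2 - 2 * n**2 / 3 + 5 * n**3 / 16 + 41 * n**4 / 180,
        13 * n**2 / 48 - 3 * n**3 / 5 + 557 * n**4 / 1440,
        61 * n**3 / 240 - 103 * n**4 / 140,
        49561 * n**4 / 161280,
    ])
    beta = np.array([
        n / 2 - 2 * n**2 / 3 + 37 * n**3 / 96 - n**4 / 360,
        n**2 / 48 + n**3 / 15 - 437 * n**4 / 1440,
        17 * n**3 / 480 - 37 * n**4 / 840,
        4397 * n**4 / 161280,
    ])
    return alpha, beta


def _rectifying_radius(a: float, n: float) -> float:
    return a / (1 + n) * (1 + n**2 / 4 + n**4 / 64)


def _conformal_lat_tan(phi: float, e: float) -> float:
    s = math.sin(phi)
    return math.sinh(math.atanh(s) - e * math.atanh(e * s))


def _meridian_xi(phi: float, e: float, alpha: np.ndarray) -> float:
    """Scaled meridian arc (xi at the central meridian) for latitude phi."""
    xi_p = math.atan(_conformal_lat_tan(phi, e))
    return xi_p + float(sum(alpha[j] * math.sin(2 * (j + 1) * xi_p) for j in range(4)))


def wgs84_to_plane(lat: float, lon: float, spec: ProjectionSpec = ProjectionSpec()) -> tuple[float, float]:
    """Forward transverse-Mercator projection: (lat, lon) deg -> (N, E) m."""
    if not (-90.0 < lat < 90.0):
        raise ValueError("latitude must lie strictly between the poles")
    n = spec.f / (2 - spec.f)
    e = math.sqrt(spec.f * (2 - spec.f))
    alpha, _ = _series_coeffs(n)
    A = _rectifying_radius(spec.a, n)

    phi = math.radians(lat)
    dlam = math.radians(lon - spec.lon0)
    tau = _conformal_lat_tan(phi, e)
    xi_p = math.atan2(tau, math.cos(dlam))
    eta_p = math.asinh(math.sin(dlam) / math.hypot(tau, math.cos(dlam)))
    xi = xi_p + float(sum(
        alpha[j] * math.sin(2 * (j + 1) * xi_p) * math.cosh(2 * (j + 1) * eta_p)
        for j in range(4)
    ))
    eta = eta_p + float(sum(
        alpha[j] * math.cos(2 * (j + 1) * xi_p) * math.sinh(2 * (j + 1) * eta_p)
        for j in range(4)
    ))
    m0 = A * _meridian_xi(math.radians(spec.lat0), e, alpha)
    N = spec.false_northing + spec.k0 * (A * xi - m0)
    E = spec.false_easting + spec.k0 * A * eta
    return N, E


def plane_to_wgs84(N: float, E: float, spec: ProjectionSpec = ProjectionSpec()) -> tuple[float, float]:
    """Inverse transverse-Mercator projection: (N, E) m -> (lat, lon) deg."""
    n = spec.f / (2 - spec.f)
    e = math.sqrt(spec.f * (2 - spec.f))
    alpha, beta = _series_coeffs(n)
    A = _rectifying_radius(spec.a, n)
    m0 = A * _meridian_xi(math.radians(spec.lat0), e, alpha)

    xi = (N - spec.false_northing + spec.k0 * m0) / (spec.k0 * A)
    eta = (E - spec.false_easting) / (spec.k0 * A)
    xi_p = xi - float(sum(
        beta[j] * math.sin(2 * (j + 1) * xi) * math.cosh(2 * (j + 1) * eta)
        for j in range(4)
    ))
    eta_p = eta - float(sum(
        beta[j] * math.cos(2 * (j + 1) * xi) * math.sinh(2 * (j + 1) * eta)
        for j in range(4)
    ))
    tau_p = math.sin(xi_p) / math.hypot(math.sinh(eta_p), math.cos(xi_p))
    dlam = math.atan2(math.sinh(eta_p), math.cos(xi_p))

    # invert the conformal latitude by fixed point on the isometric form
    chi = math.atan(tau_p)
    phi = chi
    for _ in range(12):
        s = math.sin(phi)
        phi_next = 2 * math.atan(
            math.tan(math.pi / 4 + chi / 2)
            * ((1 + e * s) / (1 - e * s)) ** (e / 2)
        ) - math.pi / 2
        if abs(phi_next - phi) < 1e-15:
            phi = phi_next
            break
        phi = phi_next
    return math.degrees(phi), spec.lon0 + math.degrees(dlam)


def accumulate_track(
    seed: tuple[float, float],
    movements: Iterable[tuple[float, float, float]],
    spec: ProjectionSpec = ProjectionSpec(),
    declination: float = DEFAULT_DECLINATION,
) -> list[TrackPoint]:
    """Dead-reckon a georeferenced track from a GPS seed.

    ``seed`` is the (lat, lon) of the first GPS fix; ``movements`` are
    ordered per-segment tuples (dX, dY, mean azimuth deg).  Only the seed
    comes from GPS — every following point is produced by the INS via the
    heading correction, the device-to-plane rotation and the cumulative
    plane update, then converted back to (lat, lon).
    """
    lat, lon = seed
    N, E = wgs84_to_plane(lat, lon, spec)
    track = [TrackPoint(N=N, E=E, lat=lat, lon=lon, source="GPS", segment_id=-1)]
    for k, (dX, dY, azimuth) in enumerate(movements):
        theta = heading_correction(azimuth, declination)
        dN, dE = displacement_to_plane(dX, dY, theta)
        N, E = N + dN, E + dE
        plat, plon = plane_to_wgs84(N, E, spec)
        track.append(TrackPoint(N=N, E=E, lat=plat, lon=plon, source="INS", segment_id=k, theta=theta))
    return track


def track_to_geojson(track: list[TrackPoint]) -> dict:
    """GeoJSON FeatureCollection: the track as a LineString plus one Point
    per position (properties carry provenance and plane coordinates)."""
    coords = [[p.lon, p.lat] for p in track]
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords},
            "properties": {"n_points": len(track)},
        }
    ]
    for p in track:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                "properties": {
                    "N": p.N, "E": p.E, "source": p.source,
                    "segment_id": p.segment_id,
                    "theta": None if math.isnan(p.theta) else p.theta,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
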
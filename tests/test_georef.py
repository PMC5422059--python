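"""Headings, the device-to-plane rotation, the projection, and tracks."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from branchnav.georef import (
    ProjectionSpec,
    accumulate_track,
    displacement_to_plane,
    heading_correction,
    plane_to_wgs84,
    wgs84_to_plane,
)

SPEC = ProjectionSpec()


class TestHeading:
    @pytest.mark.parametrize(
        "azimuth,declination,expected",
        [
            (100.0, -6.13, 106.13),
            (42.0, 0.0, 42.0),
            (358.0, -6.13, 4.13),
            (3.0, 6.0, 357.0),
        ],
    )
    def test_declination_correction_wraps(self, azimuth, declination, expected):
        assert heading_correction(azimuth, declination) == pytest.approx(expected)


class TestPlaneRotation:
    @pytest.mark.parametrize(
        "dX,dY,theta,expected",
        [
            (0.0, 1.0, 0.0, (1.0, 0.0)),     # north-pointing step
            (0.0, 1.0, 90.0, (0.0, 1.0)),    # east-pointing step
            (0.0, 0.5, 6.13, (0.49714, 0.05339)),
            (1.0, 0.0, 0.0, (0.0, 1.0)),     # device X maps 90 deg right
        ],
    )
    def test_rotation(self, dX, dY, theta, expected):
        dN, dE = displacement_to_plane(dX, dY, theta)
        assert dN == pytest.approx(expected[0], abs=1e-5)
        assert dE == pytest.approx(expected[1], abs=1e-5)

    def test_norm_preserved(self, rng):
        for _ in range(50):
            dX, dY = rng.normal(0, 2, 2)
            theta = rng.uniform(0, 360)
            dN, dE = displacement_to_plane(dX, dY, theta)
            assert math.hypot(dN, dE) == pytest.approx(math.hypot(dX, dY))


class TestProjection:
    def test_origin_maps_to_false_origin(self):
        N, E = wgs84_to_plane(SPEC.lat0, SPEC.lon0, SPEC)
        assert N == pytest.approx(SPEC.false_northing, abs=1e-6)
        assert E == pytest.approx(SPEC.false_easting, abs=1e-6)

    def test_survey_start_point_round_trip(self):
        """The recorded course origin survives plane->geo->plane to < 1 mm."""
        N0, E0 = 1043915.9141, 831420.7374
        lat, lon = plane_to_wgs84(N0, E0, SPEC)
        N1, E1 = wgs84_to_plane(lat, lon, SPEC)
        assert N1 == pytest.approx(N0, abs=1e-3)
        assert E1 == pytest.approx(E0, abs=1e-3)

    def test_round_trip_grid(self):
        for lat in (-3.0, 2.0, 4.6, 8.0):
            for lon in (-77.0, -75.5, -72.0):
                N, E = wgs84_to_plane(lat, lon, SPEC)
                lat2, lon2 = plane_to_wgs84(N, E, SPEC)
                assert lat2 == pytest.approx(lat, abs=1e-8)
                assert lon2 == pytest.approx(lon, abs=1e-8)

    def test_one_meter_east_is_one_meter_geodesic(self):
        """Independent check against the ellipsoid normal radius."""
        lat1, lon1 = plane_to_wgs84(1000000.0, 1000000.0, SPEC)
        lat2, lon2 = plane_to_wgs84(1000000.0, 1000001.0, SPEC)
        e2 = SPEC.f * (2 - SPEC.f)
        phi = math.radians(lat1)
        nrad = SPEC.a / math.sqrt(1 - e2 * math.sin(phi) ** 2)
        d = nrad * math.cos(phi) * math.radians(lon2 - lon1)
        assert d == pytest.approx(1.0, rel=1e-3)

    def test_northing_matches_meridian_arc_quadrature(self):
        """Series northing along the central meridian vs direct quadrature."""
        e2 = SPEC.f * (2 - SPEC.f)

        def meridian_radius(phi):
            return SPEC.a * (1 - e2) / (1 - e2 * math.sin(phi) ** 2) ** 1.5

        for lat in (2.0, 5.0, 7.5):
            arc, _ = quad(meridian_radius, math.radians(SPEC.lat0), math.radians(lat))
            N, E = wgs84_to_plane(lat, SPEC.lon0, SPEC)
            assert N - SPEC.false_northing == pytest.approx(arc, abs=1e-3)
            assert E == pytest.approx(SPEC.false_easting, abs=1e-6)

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            wgs84_to_plane(90.0, 0.0, SPEC)


class TestTrack:
    SEED = (4.99, -75.60)

    def test_seed_only(self):
        track = accumulate_track(self.SEED, [], SPEC)
        assert len(track) == 1
        assert track[0].source == "GPS"

    def test_single_north_step(self):
        """A 1 m step whose azimuth equals the declination heads true north."""
        track = accumulate_track(self.SEED, [(0.0, 1.0, -6.13)], SPEC, declination=-6.13)
        assert len(track) == 2
        assert track[1].N - track[0].N == pytest.approx(1.0, abs=1e-9)
        assert track[1].E - track[0].E == pytest.approx(0.0, abs=1e-9)
        assert track[1].source == "INS"

    def test_point_count_and_provenance(self, rng):
        moves = [(0.0, float(rng.uniform(0.5, 3.75)), float(rng.uniform(0, 360))) for _ in range(20)]
        track = accumulate_track(self.SEED, moves, SPEC)
        assert len(track) == 21
        assert [p.source for p in track] == ["GPS"] + ["INS"] * 20

    def test_plane_and_ellipsoid_agree(self, rng):
        moves = [(0.0, 2.0, float(rng.uniform(0, 360))) for _ in range(5)]
        for p in accumulate_track(self.SEED, moves, SPEC):
            N, E = wgs84_to_plane(p.lat, p.lon, SPEC)
            assert N == pytest.approx(p.N, abs=1e-3)
            assert E == pytest.approx(p.E, abs=1e-3)

    def test_heading_rotation_equivariance(self):
        """Rotating all azimuths by +90 deg rotates the track by +90 deg
        (N, E) -> (-E, N) about the seed."""
        moves = [(0.3, 1.0, 20.0), (0.0, 2.0, 110.0), (-0.2, 1.5, 300.0)]
        rotated = [(dx, dy, az + 90.0) for dx, dy, az in moves]
        base = accumulate_track(self.SEED, moves, SPEC)
        rot = accumulate_track(self.SEED, rotated, SPEC)
        N0, E0 = base[0].N, base[0].E
        for p, q in zip(base[1:], rot[1:]):
            dN, dE = p.N - N0, p.E - E0
            assert q.N - N0 == pytest.approx(-dE, abs=1e-9)
            assert q.E - E0 == pytest.approx(dN, abs=1e-9)

    def test_u_shaped_walk_steps_match_truth(self):
        """End-to-end: pipeline step vectors track the generator truth."""
        from branchnav.motion_detect import build_mask
        from branchnav.ins_nav import compute_kinematics
        from branchnav.pipeline import segment_headings
        from branchnav.synthgen import WalkSpec, gen_walk_trace

        lengths = [1.5] * 3 + [0.75] * 2 + [1.5] * 3
        headings = [0.0] * 3 + [90.0] * 2 + [180.0] * 3  # a U turn
        spec = WalkSpec(step_lengths=lengths, headings=headings, seed=11)
        trace, truth = gen_walk_trace(spec)
        mask = build_mask(trace, mode="NM")
        assert len(mask.segments) == len(lengths)
        profile = compute_kinematics(trace, mask)
        segs_hdg = segment_headings(trace, mask)
        moves = [
            (float(profile.disp_cal[k, 0]), float(profile.disp_cal[k, 1]), segs_hdg[k])
            for k in range(len(mask.segments))
        ]
        track = accumulate_track(self.SEED, moves, SPEC)
        N0, E0 = track[0].N, track[0].E
        est = np.array([[p.N - N0, p.E - E0] for p in track[1:]])
        true = np.asarray(truth.track)
        step_est = np.diff(est, axis=0, prepend=[[0.0, 0.0]])
        step_true = np.diff(true, axis=0, prepend=[[0.0, 0.0]])
        step_err = np.hypot(*(step_est - step_true).T)
        assert float(step_err.mean()) <= 0.15
        assert math.hypot(*(est[-1] - true[-1])) <= 0.15 * len(lengths)
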
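"""Rotation conversions against an independent matrix oracle (scipy),
plus the attitude-filter behaviours on synthetic streams."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import tacklecoach as tc
from tacklecoach.orientation import quat_to_matrix
from tacklecoach.synth import stream_from_trajectory


def to_scipy(q: tc.Quaternion) -> Rotation:
    return Rotation.from_quat([q.x, q.y, q.z, q.w])


unit_quats = st.builds(
    lambda v: tc.quat_normalize(tc.Quaternion.from_array(v)),
    st.lists(st.floats(-1, 1), min_size=4, max_size=4).filter(
        lambda v: sum(x * x for x in v) > 1e-4
    ),
)


class TestQuaternionGroup:
    def test_identity_element(self, random_quats):
        e = tc.Quaternion.identity()
        for q in random_quats:
            assert np.allclose(tc.quat_multiply(e, q).as_array(), q.as_array())

    def test_inverse_composes_to_identity(self, random_quats):
        for q in random_quats:
            prod = tc.quat_multiply(q, tc.quat_inverse(q))
            assert np.allclose(prod.as_array(), [1, 0, 0, 0], atol=1e-12)

    def test_product_matches_rotation_matrix_composition(self, random_quats):
        for a, b in zip(random_quats[::2], random_quats[1::2]):
            ours = quat_to_matrix(tc.quat_multiply(a, b))
            oracle = to_scipy(a).as_matrix() @ to_scipy(b).as_matrix()
            assert np.allclose(ours, oracle, atol=1e-12)

    def test_zero_quaternion_is_a_degenerate_rotation(self):
        zero = tc.Quaternion(0, 0, 0, 0)
        with pytest.raises(tc.DegenerateRotationError):
            tc.quat_normalize(zero)
        with pytest.raises(tc.DegenerateRotationError):
            tc.quat_inverse(zero)


class TestAxisAngle:
    def test_printed_log_reading1_reconstructs_its_quaternion(self):
        # angle 0.07 rad about (-0.14, 0.83, -0.54) -> (1.00, 0.00, 0.03, -0.02)
        q = tc.axis_angle_to_quat(tc.AxisAngle(0.07, (-0.14, 0.83, -0.54)))
        assert [round(v, 2) for v in q.as_array()] == [1.00, 0.00, 0.03, -0.02]

    def test_all_logged_readings_reconstruct_their_quaternions(self, sample_stream):
        for r in sample_stream:
            q = tc.axis_angle_to_quat(tc.AxisAngle(
                r.axis_angle_a_cal,
                (r.axis_angle_x_cal, r.axis_angle_y_cal, r.axis_angle_z_cal)))
            got = [round(v, 2) + 0.0 for v in q.as_array()]
            logged = [r.quat_0_cal, r.quat_1_cal, r.quat_2_cal, r.quat_3_cal]
            assert got == pytest.approx(logged, abs=0.01)

    def test_zero_angle_maps_to_identity_and_back(self):
        q = tc.axis_angle_to_quat(tc.AxisAngle(0.0, (0.0, 0.0, 1.0)))
        assert q == tc.Quaternion.identity()
        aa = tc.quat_to_axis_angle(q)
        assert aa.angle == 0.0 and aa.axis == (1.0, 0.0, 0.0)

    def test_quarter_turn_about_z_rotates_x_to_y(self):
        q = tc.axis_angle_to_quat(tc.AxisAngle(math.pi / 2, (0, 0, 1)))
        assert np.allclose(tc.rotate_vector(q, (1, 0, 0)), (0, 1, 0), atol=1e-12)

    def test_round_trip_is_identity(self, random_quats):
        for q in random_quats:
            back = tc.axis_angle_to_quat(tc.quat_to_axis_angle(q))
            assert tc.angle_between(q, back) < 1e-9


class TestEuler:
    def test_identity_quaternion_has_zero_angles(self):
        e = tc.quat_to_euler(tc.Quaternion.identity())
        assert (e.roll, e.pitch, e.yaw) == (0.0, 0.0, 0.0)
        assert not e.gimbal_lock

    def test_matches_matrix_decomposition_oracle(self, random_quats):
        # scipy 'ZYX' intrinsic = aerospace yaw-pitch-roll
        for q in random_quats + [tc.quat_normalize(
                tc.Quaternion(1.00, 0.00, 0.03, -0.02))]:
            e = tc.quat_to_euler(q)
            yaw, pitch, roll = to_scipy(q).as_euler("ZYX")
            assert (e.roll, e.pitch, e.yaw) == pytest.approx(
                (roll, pitch, yaw), abs=1e-9)

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(unit_quats)
    def test_round_trip_identity_away_from_gimbal_lock(self, q):
        e = tc.quat_to_euler(q)
        if abs(e.pitch) > math.radians(80):
            return
        back = tc.euler_to_quat(e)
        assert tc.angle_between(q, back) < 1e-6

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(unit_quats)
    def test_sign_of_quaternion_never_matters(self, q):
        neg = tc.Quaternion.from_array(-q.as_array())
        assert tc.quat_to_euler(q) == tc.quat_to_euler(neg)
        a, b = tc.quat_to_axis_angle(q), tc.quat_to_axis_angle(neg)
        assert a.angle == b.angle and a.axis == b.axis

    def test_gimbal_proximity_is_flagged_not_fatal(self):
        q = tc.euler_to_quat(tc.EulerAngles(0.3, math.pi / 2, 0.1))
        e = tc.quat_to_euler(q)
        assert e.gimbal_lock
        assert e.pitch == pytest.approx(math.pi / 2, abs=1e-6)


class TestRotateVector:
    def test_identity_and_half_turn(self, rng):
        v = rng.normal(size=3)
        assert np.allclose(tc.rotate_vector(tc.Quaternion.identity(), v), v)
        half_z = tc.axis_angle_to_quat(tc.AxisAngle(math.pi, (0, 0, 1)))
        assert np.allclose(tc.rotate_vector(half_z, (1, 0, 0)), (-1, 0, 0),
                           atol=1e-12)

    def test_matches_matrix_product_and_preserves_norm(self, random_quats, rng):
        for q in random_quats:
            v = rng.normal(size=3)
            got = tc.rotate_vector(q, v)
            assert np.allclose(got, to_scipy(q).as_matrix() @ v, atol=1e-10)
            assert np.linalg.norm(got) == pytest.approx(np.linalg.norm(v))


class TestEstimateOrientation:
    def test_passthrough_returns_normalised_logged_quaternions(self, sample_stream):
        quats = tc.estimate_orientation(sample_stream, "passthrough")
        assert len(quats) == 4
        for q, r in zip(quats, sample_stream):
            assert q.norm() == pytest.approx(1.0, abs=1e-12)
            assert tc.angle_between(q, tc.quat_normalize(r.quaternion())) < 1e-12

    def test_passthrough_enforces_sign_continuity(self, sample_stream):
        import dataclasses
        readings = [dataclasses.replace(
            r, quat_0_cal=-r.quat_0_cal, quat_1_cal=-r.quat_1_cal,
            quat_2_cal=-r.quat_2_cal, quat_3_cal=-r.quat_3_cal)
            if i == 2 else r for i, r in enumerate(sample_stream.readings)]
        quats = tc.estimate_orientation(tc.ImuStream(readings=readings))
        dots = [float(a.as_array() @ b.as_array())
                for a, b in zip(quats, quats[1:])]
        assert all(d > 0 for d in dots)

    def test_complementary_filter_recovers_static_pitch_30(self):
        true_q = tc.axis_angle_to_quat(tc.AxisAngle(math.radians(30), (0, 1, 0)))
        t = np.arange(0.0, 2500.0, 1000.0 / 51.2)
        stream = stream_from_trajectory(t, [true_q] * len(t))
        quats = tc.estimate_orientation(stream, "complementary")
        err = math.degrees(tc.angle_between(quats[-1], true_q))
        assert err < 1.0
        assert math.degrees(tc.quat_to_euler(quats[-1]).pitch) == pytest.approx(
            30.0, abs=1.0)

    def test_gyro_integration_of_constant_z_rate(self):
        # 10 deg/s about Z for 1 s -> yaw 10 deg (closed-form integral)
        t = np.arange(0.0, 1000.0 + 1e-9, 1000.0 / 51.2)
        quats_true = [tc.axis_angle_to_quat(
            tc.AxisAngle(math.radians(10.0 * tk / 1000.0), (0, 0, 1)))
            for tk in t]
        stream = stream_from_trajectory(t, quats_true)
        est = tc.estimate_orientation(stream, "gyro")
        yaw = math.degrees(tc.quat_to_euler(est[-1]).yaw)
        assert yaw == pytest.approx(10.0 * t[-1] / 1000.0, abs=0.1)

    def test_fusion_method_requires_finite_channels(self, sample_stream):
        import dataclasses
        readings = [dataclasses.replace(r, mag_x_cal=float("nan"))
                    for r in sample_stream.readings]
        with pytest.raises(tc.CapabilityError):
            tc.estimate_orientation(tc.ImuStream(readings=readings),
                                    "complementary")


@settings(max_examples=1000, derandomize=True, deadline=None)
@given(unit_quats)
def test_conversion_pairs_are_mutually_inverse(q):
    via_aa = tc.axis_angle_to_quat(tc.quat_to_axis_angle(q))
    assert tc.angle_between(q, via_aa) < 1e-9
    e = tc.quat_to_euler(q)
    if abs(e.pitch) < math.pi / 2 - 0.01:
        assert tc.angle_between(q, tc.euler_to_quat(e)) < 1e-6
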
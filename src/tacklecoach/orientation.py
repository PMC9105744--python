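"""Rotation algebra and attitude estimation for torso-mounted IMUs.

Rotations are carried as unit quaternions ``(w, x, y, z)`` with w the
scalar part; q and -q describe the same rotation and all conversions
here are insensitive to that sign.  Euler angles follow the aerospace
ZYX (yaw-pitch-roll) convention:

    roll  = atan2(2(wx + yz), 1 - 2(x^2 + y^2))      about X
    pitch = asin(2(wy - zx))                          about Y
    yaw   = atan2(2(wz + xy), 1 - 2(y^2 + z^2))      about Z

with the sensor worn between the scapulae so that Y runs along the
spine and X across the shoulders.  Angles are radians internally;
degrees appear only at the user interface.

When a log carries the onboard fusion quaternion, ``estimate_orientation``
in *passthrough* mode normalises it and enforces sign continuity.  When
only raw channels are available, a complementary filter integrates the
gyroscope and leans each step a small, configurable fraction toward the
accelerometer/magnetometer (gravity + heading) attitude fix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

GRAVITY = 9.81  # m/s^2
#: fraction of each step's gyro prediction blended toward the
#: accelerometer/magnetometer attitude fix (per sample).
DEFAULT_FUSION_GAIN = 0.02


class DegenerateRotationError(ValueError):
    """A zero-norm quaternion cannot represent a rotation."""


class CapabilityError(ValueError):
    """The stream lacks the channels the selected method requires."""


@dataclass(frozen=True)
class Quaternion:
    """A rotation quaternion (w, x, y, z); w is the scalar part."""

    w: float
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array()))

    @staticmethod
    def identity() -> "Quaternion":
        return Quaternion(1.0, 0.0, 0.0, 0.0)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Quaternion":
        w, x, y, z = (float(v) for v in a)
        return Quaternion(w, x, y, z)


@dataclass(frozen=True)
class AxisAngle:
    """A rotation of ``angle`` radians (>= 0) about a unit ``axis``."""

    angle: float
    axis: tuple[float, float, float]

    def axis_array(self) -> np.ndarray:
        return np.array(self.axis, dtype=float)


@dataclass(frozen=True)
class EulerAngles:
    """Aerospace ZYX roll/pitch/yaw in radians.

    ``gimbal_lock`` is set when |pitch| reached +-pi/2 within numerical
    precision, where roll and yaw are no longer separately identifiable.
    """

    roll: float
    pitch: float
    yaw: float
    gimbal_lock: bool = False


def quat_normalize(q: Quaternion) -> Quaternion:
    n = q.norm()
    if n < 1e-12:
        raise DegenerateRotationError("cannot normalise a zero quaternion")
    return Quaternion.from_array(q.as_array() / n)


def quat_canonical(q: Quaternion) -> Quaternion:
    """Unit quaternion with a canonical sign (first nonzero component > 0)."""
    q = quat_normalize(q)
    a = q.as_array()
    for v in a:
        if abs(v) > 1e-12:
            return Quaternion.from_array(-a) if v < 0 else q
    return q


def quat_multiply(a: Quaternion, b: Quaternion) -> Quaternion:
    """Hamilton product a*b: the rotation b followed by the rotation a."""
    w1, x1, y1, z1 = a.w, a.x, a.y, a.z
    w2, x2, y2, z2 = b.w, b.x, b.y, b.z
    return Quaternion(
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    )


def quat_inverse(q: Quaternion) -> Quaternion:
    n2 = q.norm() ** 2
    if n2 < 1e-24:
        raise DegenerateRotationError("cannot invert a zero quaternion")
    return Quaternion(q.w / n2, -q.x / n2, -q.y / n2, -q.z / n2)


def rotate_vector(q: Quaternion, v: Sequence[float]) -> np.ndarray:
    """Apply the rotation q to a 3-vector (equivalent to R(q) @ v)."""
    q = quat_normalize(q)
    u = np.array([q.x, q.y, q.z], dtype=float)
    vv = np.asarray(v, dtype=float)
    # v' = v + 2 u x (u x v + w v)
    return vv + 2.0 * np.cross(u, np.cross(u, vv) + q.w * vv)


def quat_to_matrix(q: Quaternion) -> np.ndarray:
    """The 3x3 rotation matrix of q (sensor-to-world)."""
    q = quat_normalize(q)
    w, x, y, z = q.w, q.x, q.y, q.z
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(r: np.ndarray) -> Quaternion:
    """Quaternion of a proper rotation matrix (Shepperd's method)."""
    r = np.asarray(r, dtype=float)
    tr = np.trace(r)
    if tr > 0:
        s = math.sqrt(tr + 1.0) * 2.0
        q = Quaternion(
            0.25 * s,
            (r[2, 1] - r[1, 2]) / s,
            (r[0, 2] - r[2, 0]) / s,
            (r[1, 0] - r[0, 1]) / s,
        )
    else:
        i = int(np.argmax(np.diag(r)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(r[i, i] - r[j, j] - r[k, k] + 1.0, 0.0)) * 2.0
        v = [0.0, 0.0, 0.0]
        v[i] = 0.25 * s
        v[j] = (r[j, i] + r[i, j]) / s
        v[k] = (r[k, i] + r[i, k]) / s
        q = Quaternion((r[k, j] - r[j, k]) / s, *v)
    return quat_canonical(q)


def rotation_angle(q: Quaternion) -> float:
    """The rotation angle of q in radians, in [0, pi]."""
    q = quat_canonical(q)  # w >= 0, so atan2 lands in [0, pi/2]
    return 2.0 * math.atan2(math.sqrt(q.x**2 + q.y**2 + q.z**2), q.w)


def angle_between(a: Quaternion, b: Quaternion) -> float:
    """Geodesic angle between two rotations, radians in [0, pi]."""
    return rotation_angle(quat_multiply(quat_inverse(a), b))


def axis_angle_to_quat(aa: AxisAngle) -> Quaternion:
    """w = cos(angle/2), (x,y,z) = sin(angle/2) * axis."""
    angle = float(aa.angle)
    axis = aa.axis_array()
    n = float(np.linalg.norm(axis))
    # a negative angle is accepted and folds into the axis direction
    if abs(angle) <= 1e-12 or n < 1e-12:
        return Quaternion.identity()
    axis = axis / n
    h = angle / 2.0
    s = math.sin(h)
    return Quaternion(math.cos(h), s * axis[0], s * axis[1], s * axis[2])


def quat_to_axis_angle(q: Quaternion) -> AxisAngle:
    """Canonical axis-angle of q: angle in [0, pi].

    The identity rotation has no defined axis; by convention it is
    reported as angle 0 about (1, 0, 0).
    """
    q = quat_canonical(q)
    vn = math.sqrt(q.x**2 + q.y**2 + q.z**2)
    angle = 2.0 * math.atan2(vn, q.w)
    if vn < 1e-12:
        return AxisAngle(0.0, (1.0, 0.0, 0.0))
    return AxisAngle(angle, (q.x / vn, q.y / vn, q.z / vn))


#: |sin(pitch)| beyond which roll and yaw become degenerate and the
#: result is flagged as gimbal-proximate.
_GIMBAL_SIN_PITCH = 1.0 - 1e-9


def quat_to_euler(q: Quaternion) -> EulerAngles:
    """Roll/pitch/yaw (aerospace ZYX) of a unit quaternion.

    The pitch argument is clamped to [-1, 1]; values at the clamp are
    flagged via ``gimbal_lock`` rather than raised.
    """
    q = quat_canonical(q)
    w, x, y, z = q.w, q.x, q.y, q.z
    sp = 2.0 * (w * y - z * x)
    gimbal = abs(sp) >= _GIMBAL_SIN_PITCH
    sp = max(-1.0, min(1.0, sp))
    return EulerAngles(
        roll=math.atan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y)),
        pitch=math.asin(sp),
        yaw=math.atan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z)),
        gimbal_lock=gimbal,
    )


def euler_to_quat(e: EulerAngles) -> Quaternion:
    """Quaternion of ZYX roll/pitch/yaw (inverse of :func:`quat_to_euler`)."""
    cr, sr = math.cos(e.roll / 2), math.sin(e.roll / 2)
    cp, sp = math.cos(e.pitch / 2), math.sin(e.pitch / 2)
    cy, sy = math.cos(e.yaw / 2), math.sin(e.yaw / 2)
    return Quaternion(
        cy * cp * cr + sy * sp * sr,
        cy * cp * sr - sy * sp * cr,
        cy * sp * cr + sy * cp * sr,
        sy * cp * cr - cy * sp * sr,
    )


def _quat_exp(rotvec: np.ndarray) -> Quaternion:
    """Unit quaternion of a rotation vector (axis * angle, radians)."""
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-15:
        return Quaternion.identity()
    return axis_angle_to_quat(AxisAngle(angle, tuple(rotvec / angle)))


def _slerp(a: Quaternion, b: Quaternion, t: float) -> Quaternion:
    """Spherical interpolation from a (t=0) to b (t=1), sign-aligned."""
    av, bv = a.as_array(), b.as_array()
    if float(av @ bv) < 0:
        bv = -bv
    dot = max(-1.0, min(1.0, float(av @ bv)))
    theta = math.acos(dot)
    if theta < 1e-9:
        return quat_normalize(Quaternion.from_array((1 - t) * av + t * bv))
    s = math.sin(theta)
    return quat_normalize(
        Quaternion.from_array(
            (math.sin((1 - t) * theta) / s) * av + (math.sin(t * theta) / s) * bv
        )
    )


def attitude_from_accel_mag(
    accel: Sequence[float], mag: Sequence[float]
) -> Quaternion:
    """Absolute attitude fix from one accelerometer + magnetometer sample.

    A TRIAD-style construction: the measured gravity direction fixes the
    world up axis, the horizontal component of the magnetic field fixes
    north.  World frame: X north, Z up, Y = Z x X.
    """
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    if np.linalg.norm(a) < 1e-9 or np.linalg.norm(m) < 1e-9:
        raise CapabilityError("accelerometer/magnetometer sample is degenerate")
    up_s = a / np.linalg.norm(a)  # specific force points up when static
    m_h = m - (m @ up_s) * up_s
    if np.linalg.norm(m_h) < 1e-9:
        raise CapabilityError("magnetic field is vertical; heading unobservable")
    north_s = m_h / np.linalg.norm(m_h)
    east_like = np.cross(up_s, north_s)
    # rows of R (sensor->world) are the world axes in sensor coordinates
    r = np.vstack([north_s, east_like, up_s])
    return matrix_to_quat(r)


def _require_finite(arrs: dict[str, np.ndarray]) -> None:
    for name, a in arrs.items():
        if a.size == 0 or not np.all(np.isfinite(a)):
            raise CapabilityError(f"channel {name} is missing or non-finite")


def estimate_orientation(
    stream,
    method: str = "passthrough",
    *,
    gain: float = DEFAULT_FUSION_GAIN,
) -> list[Quaternion]:
    """Per-sample orientation quaternions for an IMU stream.

    Methods
    -------
    ``"passthrough"``
        Normalise the onboard fusion quaternions and flip signs for
        continuity (each sample's quaternion is kept in the same
        hemisphere as its predecessor).
    ``"complementary"``
        Integrate the gyroscope and blend each step a fraction ``gain``
        toward the accelerometer/magnetometer attitude fix; initialised
        from the first sample's fix so a static stream converges
        immediately.
    ``"gyro"``
        Pure gyroscope integration from the first sample's
        accelerometer/magnetometer fix (drifts; useful for diagnostics).
    """
    readings = list(stream)
    if method == "passthrough":
        out: list[Quaternion] = []
        prev: Quaternion | None = None
        for r in readings:
            q = quat_normalize(r.quaternion())
            if prev is not None and float(q.as_array() @ prev.as_array()) < 0:
                q = Quaternion.from_array(-q.as_array())
            out.append(q)
            prev = q
        return out

    if method not in ("complementary", "gyro"):
        raise ValueError(f"unknown orientation method {method!r}")
    if not readings:
        return []

    t = np.array([r.timestamp_cal for r in readings]) / 1000.0  # s
    acc = np.array(
        [[r.ln_accel_x_cal, r.ln_accel_y_cal, r.ln_accel_z_cal] for r in readings]
    )
    gyr = np.deg2rad(
        np.array([[r.gyro_x_cal, r.gyro_y_cal, r.gyro_z_cal] for r in readings])
    )
    mag = np.array([[r.mag_x_cal, r.mag_y_cal, r.mag_z_cal] for r in readings])
    _require_finite({"accelerometer": acc, "gyroscope": gyr, "magnetometer": mag})

    q = attitude_from_accel_mag(acc[0], mag[0])
    out = [q]
    for k in range(1, len(readings)):
        dt = t[k] - t[k - 1]
        # body-rate integration over [k-1, k] using the earlier sample's rate
        q = quat_multiply(q, _quat_exp(gyr[k - 1] * dt))
        if method == "complementary":
            q = _slerp(q, attitude_from_accel_mag(acc[k], mag[k]), gain)
        if float(q.as_array() @ out[-1].as_array()) < 0:
            q = Quaternion.from_array(-q.as_array())
        out.append(quat_normalize(q))
    return out
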
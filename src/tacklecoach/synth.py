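"""Synthetic IMU streams replicating the static tackle-drill protocol.

The drill this emulates: a player calibrates standing in the approach
posture, then performs ten static tackles on a padded surface — five on
the left shoulder, five on the right — at a commanded angle of approach
(0 degrees for the safe drill; alternating +-12 degrees, just outside
the +-10 degree band, for the unsafe drill).  The simulator moves a
single sensor frame through that protocol with known ground truth:

* the torso rotates about the shoulder (X) axis, ramping smoothly from
  the reference pose to the commanded angle before each impact, holding
  it through contact, and returning;
* the accelerometers read gravity rotated into the sensor frame, and
  the wide-range channel adds a half-sine impact transient (50 ms,
  default peak 80 m/s^2) at each contact;
* the gyroscope is the numerical derivative of the orientation
  trajectory, so integrating it reproduces the trajectory;
* the magnetometer reads a fixed earth field (0.5 cgs at 60 degrees
  inclination, an arbitrary but fixed choice) rotated into the sensor
  frame;
* the onboard quaternion/axis-angle fields carry the true orientation
  perturbed by a per-sample random rotation of configurable size.

Identical seeds give bit-identical streams.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .imu_io import DEFAULT_TICKS_PER_SECOND, ImuReading, ImuStream
from .orientation import (
    AxisAngle,
    Quaternion,
    axis_angle_to_quat,
    quat_inverse,
    quat_multiply,
    quat_to_axis_angle,
    quat_to_matrix,
)
from .tackle_analysis import Shoulder

GRAVITY_MS2 = 9.81
#: earth magnetic field used by the simulator: magnitude (cgs flux) and
#: inclination (degrees below horizontal), fixed and documented.
MAG_FIELD_CGS = 0.5
MAG_INCLINATION_DEG = 60.0

DEFAULT_SAMPLE_RATE_HZ = 51.2  # gives an integer 640-tick interval
RAMP_MS = 300.0  # rise/fall time of the approach rotation
HOLD_MS = 100.0  # plateau either side of the impact instant
PULSE_MS = 50.0  # half-sine impact duration
DEFAULT_IMPACT_MS2 = 80.0  # peak impact acceleration

# Nominal raw-channel gains/offsets (ADC counts); the analysis pipeline
# only ever reads calibrated channels, raw ones are for format fidelity.
_LN_GAIN, _LN_OFFSET = 83.0, 2048.0
_WR_GAIN = -1671.0
_GYRO_GAIN = 65.5
_MAG_GAIN = 667.0
_PRESSURE_CAL, _PRESSURE_RAW = 1013.25, 20265.0
_TEMPERATURE_CAL, _TEMPERATURE_RAW = 22.0, 32200.0


@dataclass(frozen=True)
class ScriptedTackle:
    """One commanded contact: angle (degrees, + above the zero plane),
    shoulder side, impact instant (ms) and pulse peak (m/s^2)."""

    commanded_angle_deg: float
    shoulder: Shoulder
    impact_time_ms: float
    impact_magnitude: float = DEFAULT_IMPACT_MS2


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel additive Gaussian noise standard deviations.

    ``orientation_sd_deg`` perturbs the onboard quaternion by a random
    rotation whose rotation-vector components are N(0, sd) per axis.
    """

    accel_sd: float = 0.05  # m/s^2
    gyro_sd: float = 0.5  # deg/s
    mag_sd: float = 0.005  # cgs
    orientation_sd_deg: float = 0.5  # deg

    @staticmethod
    def zero() -> "NoiseModel":
        return NoiseModel(0.0, 0.0, 0.0, 0.0)


@dataclass
class TackleScript:
    """A full simulated drill: scripted contacts, noise, sampling, seed."""

    events: list[ScriptedTackle]
    noise: NoiseModel = field(default_factory=NoiseModel)
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    seed: int = 0
    base_angle_deg: float = 0.0  # constant offset held outside contacts
    tail_ms: float = 1000.0
    duration_ms: float | None = None

    def __post_init__(self) -> None:
        if not (self.sample_rate_hz > 0):
            raise ValueError("sample_rate_hz must be positive")
        times = [e.impact_time_ms for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("impact times must be strictly increasing")

    def total_duration_ms(self) -> float:
        if self.duration_ms is not None:
            return self.duration_ms
        last = self.events[-1].impact_time_ms if self.events else 0.0
        return last + self.tail_ms


@dataclass
class GroundTruth:
    """Simulator side channel: the true per-sample orientation and the
    scripted contacts, kept separate from the stream itself."""

    timestamps_ms: np.ndarray
    quaternions: list[Quaternion]
    angles_deg: np.ndarray
    events: list[ScriptedTackle]
    script: TackleScript


def default_protocol(
    seed: int = 0,
    variant: str = "safe",
    *,
    noise: NoiseModel | None = None,
    unsafe_angle_deg: float = 12.0,
    first_impact_ms: float = 2500.0,
    spacing_ms: float = 1500.0,
    n_events: int = 10,
) -> TackleScript:
    """The ten-tackle drill: five left-, five right-shoulder contacts.

    ``variant="safe"`` commands every contact at 0 degrees;
    ``variant="unsafe"`` alternates just outside the band at
    +-``unsafe_angle_deg`` (default 12, i.e. roughly ten degrees above
    and below the tolerance edge of a zero approach).
    """
    if variant not in ("safe", "unsafe"):
        raise ValueError(f"unknown protocol variant {variant!r}")
    events = []
    for k in range(n_events):
        angle = 0.0
        if variant == "unsafe":
            angle = unsafe_angle_deg if k % 2 == 0 else -unsafe_angle_deg
        events.append(
            ScriptedTackle(
                commanded_angle_deg=angle,
                shoulder=Shoulder.LEFT if k % 2 == 0 else Shoulder.RIGHT,
                impact_time_ms=first_impact_ms + k * spacing_ms,
            )
        )
    return TackleScript(events=events, noise=noise or NoiseModel(), seed=seed)


def _ramp_shape(u: np.ndarray) -> np.ndarray:
    """Raised-cosine ramp 0 -> 1 over u in [0, 1] (flat at both ends)."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def approach_angle_profile(t_ms: np.ndarray, script: TackleScript) -> np.ndarray:
    """The commanded approach angle (degrees) at each sample time."""
    angle = np.full_like(t_ms, script.base_angle_deg, dtype=float)
    for ev in script.events:
        t0 = ev.impact_time_ms
        rise = _ramp_shape((t_ms - (t0 - HOLD_MS - RAMP_MS)) / RAMP_MS)
        fall = _ramp_shape((t_ms - (t0 + HOLD_MS)) / RAMP_MS)
        angle += ev.commanded_angle_deg * (rise - fall)
    return angle


def _impact_pulse(t_ms: np.ndarray, script: TackleScript) -> np.ndarray:
    """Half-sine wide-range transient (m/s^2), peaking at each impact."""
    pulse = np.zeros_like(t_ms, dtype=float)
    for ev in script.events:
        u = (t_ms - (ev.impact_time_ms - PULSE_MS / 2.0)) / PULSE_MS
        mask = (u >= 0.0) & (u <= 1.0)
        pulse[mask] += ev.impact_magnitude * np.sin(np.pi * u[mask])
    return pulse


def mag_field_world() -> np.ndarray:
    inc = math.radians(MAG_INCLINATION_DEG)
    return MAG_FIELD_CGS * np.array([math.cos(inc), 0.0, -math.sin(inc)])


def _finite_difference_rates(
    t_ms: np.ndarray, quats: list[Quaternion]
) -> np.ndarray:
    """Body rates (deg/s) whose forward integration reproduces ``quats``."""
    n = len(quats)
    rates = np.zeros((n, 3))
    for k in range(n - 1):
        dt = (t_ms[k + 1] - t_ms[k]) / 1000.0
        aa = quat_to_axis_angle(quat_multiply(quat_inverse(quats[k]), quats[k + 1]))
        rates[k] = np.degrees(aa.angle / dt) * aa.axis_array()
    return rates


def stream_from_trajectory(
    t_ms: np.ndarray,
    quats: list[Quaternion],
    *,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    pulse: np.ndarray | None = None,
    ticks_per_second: float = DEFAULT_TICKS_PER_SECOND,
    start_ticks: float = 1_000_000.0,
    meta: dict | None = None,
) -> ImuStream:
    """Populate all 38 log fields consistently with a true orientation
    trajectory.  ``pulse`` (m/s^2, sensor Y axis) is added to the
    wide-range accelerometer only."""
    noise = noise or NoiseModel.zero()
    rng = rng or np.random.default_rng(0)
    n = len(t_ms)
    if len(quats) != n:
        raise ValueError("one quaternion per sample time is required")
    pulse = np.zeros(n) if pulse is None else pulse

    g_world = np.array([0.0, 0.0, GRAVITY_MS2])
    m_world = mag_field_world()
    rates = _finite_difference_rates(t_ms, quats)

    ticks = np.round(start_ticks + t_ms * ticks_per_second / 1000.0)
    acc_noise = rng.normal(0.0, 1.0, (n, 3)) * noise.accel_sd
    wr_noise = rng.normal(0.0, 1.0, (n, 3)) * noise.accel_sd
    gyr_noise = rng.normal(0.0, 1.0, (n, 3)) * noise.gyro_sd
    mag_noise = rng.normal(0.0, 1.0, (n, 3)) * noise.mag_sd
    ori_noise = rng.normal(0.0, 1.0, (n, 3)) * math.radians(noise.orientation_sd_deg)

    readings = []
    for k in range(n):
        rt = quat_to_matrix(quats[k]).T  # world -> sensor
        acc = rt @ g_world + acc_noise[k]
        wr = rt @ g_world + pulse[k] * np.array([0.0, 1.0, 0.0]) + wr_noise[k]
        gyr = rates[k] + gyr_noise[k]
        mag = rt @ m_world + mag_noise[k]
        nvec = ori_noise[k]
        nangle = float(np.linalg.norm(nvec))
        q_noise = (
            axis_angle_to_quat(AxisAngle(nangle, tuple(nvec / nangle)))
            if nangle > 1e-15
            else Quaternion.identity()
        )
        q_on = quat_multiply(quats[k], q_noise)
        aa = quat_to_axis_angle(q_on)
        readings.append(
            ImuReading(
                timestamp_raw=float(ticks[k]),
                timestamp_cal=float(t_ms[k]),
                ln_accel_x_raw=round(_LN_OFFSET + _LN_GAIN * acc[0]),
                ln_accel_x_cal=float(acc[0]),
                ln_accel_y_raw=round(_LN_OFFSET + _LN_GAIN * acc[1]),
                ln_accel_y_cal=float(acc[1]),
                ln_accel_z_raw=round(_LN_OFFSET + _LN_GAIN * acc[2]),
                ln_accel_z_cal=float(acc[2]),
                wr_accel_x_raw=round(_WR_GAIN * wr[0]),
                wr_accel_x_cal=float(wr[0]),
                wr_accel_y_raw=round(_WR_GAIN * wr[1]),
                wr_accel_y_cal=float(wr[1]),
                wr_accel_z_raw=round(_WR_GAIN * wr[2]),
                wr_accel_z_cal=float(wr[2]),
                gyro_x_raw=round(_GYRO_GAIN * gyr[0]),
                gyro_x_cal=float(gyr[0]),
                gyro_y_raw=round(_GYRO_GAIN * gyr[1]),
                gyro_y_cal=float(gyr[1]),
                gyro_z_raw=round(_GYRO_GAIN * gyr[2]),
                gyro_z_cal=float(gyr[2]),
                mag_x_raw=round(_MAG_GAIN * mag[0]),
                mag_x_cal=float(mag[0]),
                mag_y_raw=round(_MAG_GAIN * mag[1]),
                mag_y_cal=float(mag[1]),
                mag_z_raw=round(_MAG_GAIN * mag[2]),
                mag_z_cal=float(mag[2]),
                pressure_raw=_PRESSURE_RAW,
                pressure_cal=_PRESSURE_CAL,
                temperature_raw=_TEMPERATURE_RAW,
                temperature_cal=_TEMPERATURE_CAL,
                axis_angle_a_cal=float(aa.angle),
                axis_angle_x_cal=float(aa.axis[0]),
                axis_angle_y_cal=float(aa.axis[1]),
                axis_angle_z_cal=float(aa.axis[2]),
                quat_0_cal=float(q_on.w),
                quat_1_cal=float(q_on.x),
                quat_2_cal=float(q_on.y),
                quat_3_cal=float(q_on.z),
            )
        )
    interval = float(np.median(np.diff(ticks))) if n >= 2 else None
    return ImuStream(
        readings=readings,
        sample_interval_ticks=interval,
        irregular=False,
        ticks_per_second=ticks_per_second,
        meta=meta or {},
    )


def simulate_stream(script: TackleScript) -> tuple[ImuStream, GroundTruth]:
    """Run a script through the single-sensor-frame motion model.

    Returns the 38-field stream and a :class:`GroundTruth` side channel
    (true quaternions, true approach angles, the scripted contacts).
    Identical scripts (including seed) give bit-identical streams.
    """
    dt_ms = 1000.0 / script.sample_rate_hz
    n = int(math.floor(script.total_duration_ms() / dt_ms)) + 1
    t_ms = np.arange(n) * dt_ms
    angles = approach_angle_profile(t_ms, script)
    quats = [
        axis_angle_to_quat(AxisAngle(math.radians(a), (1.0, 0.0, 0.0)))
        for a in angles
    ]
    rng = np.random.default_rng(script.seed)
    stream = stream_from_trajectory(
        t_ms,
        quats,
        noise=script.noise,
        rng=rng,
        pulse=_impact_pulse(t_ms, script),
        meta={"seed": script.seed, "sample_rate_hz": script.sample_rate_hz},
    )
    truth = GroundTruth(
        timestamps_ms=t_ms,
        quaternions=quats,
        angles_deg=angles,
        events=list(script.events),
        script=script,
    )
    return stream, truth


def write_ground_truth(truth: GroundTruth, sink: str | Path | IO[str]) -> str:
    """Serialise the scripted contacts (not per-sample state) to JSON."""
    doc = {
        "format_version": "1",
        "sample_rate_hz": truth.script.sample_rate_hz,
        "seed": truth.script.seed,
        "events": [
            {
                "commanded_angle_deg": e.commanded_angle_deg,
                "shoulder": e.shoulder.value,
                "impact_time_ms": e.impact_time_ms,
                "impact_magnitude": e.impact_magnitude,
            }
            for e in truth.events
        ],
    }
    text = json.dumps(doc, indent=2)
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        Path(sink).write_text(text, encoding="utf-8")
    return text


def read_ground_truth_events(source: str | Path | IO[str]) -> list[ScriptedTackle]:
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    doc = json.loads(text)
    return [
        ScriptedTackle(
            commanded_angle_deg=float(e["commanded_angle_deg"]),
            shoulder=Shoulder(e["shoulder"]),
            impact_time_ms=float(e["impact_time_ms"]),
            impact_magnitude=float(e.get("impact_magnitude", DEFAULT_IMPACT_MS2)),
        )
        for e in doc["events"]
    ]


def noisy_protocol(
    seed: int, variant: str = "safe", orientation_sd_deg: float = 0.5
) -> TackleScript:
    """Convenience: the default protocol with a given orientation noise."""
    script = default_protocol(seed, variant)
    return replace(script, noise=replace(script.noise, orientation_sd_deg=orientation_sd_deg))
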
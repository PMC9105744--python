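"""Standing-pose calibration: each player's zero angle of approach.

Before a drill the player holds the approach posture (hips hinged, head
up, shoulder square to the pad) for a short still window.  The mean
orientation over that window becomes the player's reference pose; every
later orientation is expressed relative to it, so the reference *is*
the zero angle of approach.  A stillness check (maximum angular
deviation inside the window) rejects calibrations taken while the
player was moving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .orientation import (
    Quaternion,
    angle_between,
    estimate_orientation,
    quat_inverse,
    quat_multiply,
    quat_normalize,
)

#: maximum angular deviation (degrees) tolerated inside a calibration
#: window before the capture is rejected as movement.
DEFAULT_STILLNESS_DEG = 3.0
MIN_WINDOW_SAMPLES = 10


class CalibrationError(ValueError):
    """The calibration window is unusable (movement or too few samples)."""


@dataclass(frozen=True)
class ReferencePose:
    """A player's standing/approach reference orientation.

    ``dispersion_deg`` is the largest angular deviation of any windowed
    sample from the mean orientation — a stillness diagnostic.
    """

    q_ref: Quaternion
    window: tuple[float, float]
    dispersion_deg: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "q_ref": list(self.q_ref.as_array()),
            "window": list(self.window),
            "dispersion_deg": self.dispersion_deg,
        }

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "ReferencePose":
        return ReferencePose(
            q_ref=Quaternion.from_array(d["q_ref"]),
            window=(float(d["window"][0]), float(d["window"][1])),
            dispersion_deg=float(d["dispersion_deg"]),
        )


def mean_quaternion(quats: Sequence[Quaternion]) -> Quaternion:
    """Sign-aligned chordal mean of a set of rotation quaternions.

    Each quaternion is flipped into the hemisphere of the first, the
    components are averaged and the result normalised.  Accurate for
    tight clusters; not suitable for dispersions beyond ~30 degrees.
    """
    if not quats:
        raise CalibrationError("cannot average an empty set of orientations")
    ref = quats[0].as_array()
    acc = np.zeros(4)
    for q in quats:
        a = q.as_array()
        acc += -a if float(a @ ref) < 0 else a
    return quat_normalize(Quaternion.from_array(acc / len(quats)))


def capture_reference(
    stream,
    window: tuple[float, float],
    *,
    method: str = "passthrough",
    stillness_deg: float = DEFAULT_STILLNESS_DEG,
    quaternions: Sequence[Quaternion] | None = None,
) -> ReferencePose:
    """Average the orientations inside ``window`` into a reference pose.

    ``window`` is a ``(start_ms, end_ms)`` pair of calibrated
    timestamps, inclusive.  Orientations come from
    :func:`~tacklecoach.orientation.estimate_orientation` with
    ``method`` unless precomputed ``quaternions`` (one per stream
    sample) are supplied.

    Raises :class:`CalibrationError` when fewer than 10 samples fall in
    the window or when the dispersion exceeds ``stillness_deg``.
    """
    t = stream.timestamps()
    quats = (
        list(quaternions) if quaternions is not None
        else estimate_orientation(stream, method)
    )
    if len(quats) != len(t):
        raise CalibrationError("one orientation per stream sample is required")
    start, end = window
    idx = np.nonzero((t >= start) & (t <= end))[0]
    if len(idx) < MIN_WINDOW_SAMPLES:
        raise CalibrationError(
            f"calibration window holds {len(idx)} samples; "
            f"at least {MIN_WINDOW_SAMPLES} are required"
        )
    windowed = [quats[i] for i in idx]
    q_ref = mean_quaternion(windowed)
    dispersion = max(np.degrees(angle_between(q_ref, q)) for q in windowed)
    if dispersion > stillness_deg:
        raise CalibrationError(
            f"movement during calibration: dispersion {dispersion:.2f} deg "
            f"exceeds the {stillness_deg:.2f} deg stillness threshold"
        )
    return ReferencePose(q_ref=q_ref, window=(float(start), float(end)),
                         dispersion_deg=float(dispersion))


def relative_orientation(ref: ReferencePose | Quaternion, q_t: Quaternion) -> Quaternion:
    """Orientation of the sample expressed in the reference frame:
    ``inverse(q_ref) * q_t`` (identity when the player holds the
    calibrated pose)."""
    q_ref = ref.q_ref if isinstance(ref, ReferencePose) else ref
    return quat_multiply(quat_inverse(quat_normalize(q_ref)), quat_normalize(q_t))
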
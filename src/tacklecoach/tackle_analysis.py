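"""Tackle-event segmentation and traffic-light safety classification.

A tackle shows up as a short transient on the wide-range accelerometer.
Events are segmented by a threshold on the acceleration magnitude with
a refractory period, the angle of approach is measured at contact from
the calibrated relative orientation, and each event is labelled SAFE
(green) when the angle lies inside a symmetric tolerance band about the
player's zero angle of approach — by default +-10 degrees — and UNSAFE
(red) outside it.

The angle of approach is the elevation of the rotated spine axis (the
sensor Y axis) above the reference horizontal plane.  For a pure
rotation about the shoulder (X) axis this equals the relative pitch;
unlike raw Euler pitch it stays meaningful when roll and yaw mix in.
To suppress per-sample sensor noise the reported contact angle is the
mean over a short window centred on the acceleration peak; the raw
single-sample value is kept alongside it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .calibration import ReferencePose, relative_orientation
from .orientation import Quaternion, estimate_orientation, rotate_vector

#: wide-range acceleration magnitude (m/s^2) that opens an event.
DEFAULT_ACCEL_THRESHOLD = 25.0
#: quiet time (ms) below threshold required to close an event; crossings
#: closer together than this merge into one event.
DEFAULT_REFRACTORY_MS = 300.0
#: half-width (ms) of the contact window over which the reported
#: approach angle is averaged.
CONTACT_WINDOW_MS = 100.0


class Shoulder(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    UNKNOWN = "UNKNOWN"


class Label(str, enum.Enum):
    SAFE = "SAFE"
    UNSAFE = "UNSAFE"


@dataclass(frozen=True)
class ToleranceConfig:
    """The symmetric safety band about the zero angle of approach.

    ``half_width_deg`` degrees above and below zero count as safe;
    the boundary itself is safe when ``boundary_inclusive``.
    """

    half_width_deg: float = 10.0
    boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (self.half_width_deg > 0):
            raise ValueError("tolerance half-width must be positive")


@dataclass
class TackleEvent:
    """One segmented contact event.

    ``approach_angle_deg`` is the contact-window mean elevation used for
    labelling (positive above the zero plane, negative below);
    ``approach_angle_instant_deg`` is the single-sample value at the
    acceleration peak.
    """

    start_ms: float
    end_ms: float
    peak_accel: float
    approach_angle_deg: float = math.nan
    approach_angle_instant_deg: float = math.nan
    shoulder: Shoulder = Shoulder.UNKNOWN
    label: Label | None = None
    peak_index: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.start_ms < self.end_ms):
            raise ValueError("event must satisfy start < end")

    def to_dict(self) -> dict[str, Any]:
        return {
            "start_ms": self.start_ms,
            "end_ms": self.end_ms,
            "peak_accel": self.peak_accel,
            "approach_angle_deg": self.approach_angle_deg,
            "approach_angle_instant_deg": self.approach_angle_instant_deg,
            "shoulder": self.shoulder.value,
            "label": self.label.value if self.label is not None else None,
        }

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "TackleEvent":
        return TackleEvent(
            start_ms=float(d["start_ms"]),
            end_ms=float(d["end_ms"]),
            peak_accel=float(d["peak_accel"]),
            approach_angle_deg=float(d["approach_angle_deg"]),
            approach_angle_instant_deg=float(d["approach_angle_instant_deg"]),
            shoulder=Shoulder(d.get("shoulder", "UNKNOWN")),
            label=Label(d["label"]) if d.get("label") is not None else None,
        )


def detect_events(
    stream,
    accel_threshold: float = DEFAULT_ACCEL_THRESHOLD,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> list[TackleEvent]:
    """Segment impact transients into disjoint, ordered, unlabelled events.

    An event opens when the wide-range acceleration magnitude exceeds
    ``accel_threshold`` and closes once it has stayed below for
    ``refractory_ms``; crossings inside one refractory window merge.
    """
    t = stream.timestamps()
    mag = np.array([r.wr_accel_magnitude() for r in stream])
    above = mag > accel_threshold
    if not above.any():
        return []

    runs: list[tuple[int, int]] = []  # inclusive sample-index spans
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))

    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if t[s] - t[pe] < refractory_ms:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))

    events = []
    for s, e in merged:
        peak = s + int(np.argmax(mag[s : e + 1]))
        end_ms = t[e] if e > s else t[e] + 1e-6  # zero-length runs still span
        events.append(
            TackleEvent(
                start_ms=float(t[s]),
                end_ms=float(end_ms),
                peak_accel=float(mag[peak]),
                peak_index=peak,
            )
        )
    return events


def approach_angle(rel: Quaternion) -> float:
    """Signed angle of approach (degrees) of a relative orientation.

    The elevation of the rotated spine-axis (Y) unit vector above the
    reference horizontal plane: ``asin`` of its component along the
    reference vertical.  Zero at the calibrated pose; positive above
    the zero plane, negative below.
    """
    y_rot = rotate_vector(rel, (0.0, 1.0, 0.0))
    return math.degrees(math.asin(max(-1.0, min(1.0, float(y_rot[2])))))


def classify(angle_deg: float, config: ToleranceConfig | None = None) -> Label:
    """SAFE iff |angle| is within the tolerance band, else UNSAFE."""
    if config is None:
        config = ToleranceConfig()
    if not math.isfinite(angle_deg):
        raise ValueError(f"approach angle must be finite, got {angle_deg!r}")
    a = abs(angle_deg)
    inside = a <= config.half_width_deg if config.boundary_inclusive else a < config.half_width_deg
    return Label.SAFE if inside else Label.UNSAFE


def label_events(
    stream,
    events: Sequence[TackleEvent],
    reference: ReferencePose,
    config: ToleranceConfig | None = None,
    *,
    method: str = "passthrough",
    quaternions: Sequence[Quaternion] | None = None,
    contact_window_ms: float = CONTACT_WINDOW_MS,
    shoulders: Sequence[Shoulder] | None = None,
) -> list[TackleEvent]:
    """Measure the approach angle at contact and label each event.

    Returns new events carrying ``approach_angle_deg`` (contact-window
    mean, used for the label), ``approach_angle_instant_deg`` and the
    SAFE/UNSAFE label.  ``shoulders``, when given, annotates events in
    order (a protocol annotation; the side is not inferred from data).
    """
    if config is None:
        config = ToleranceConfig()
    t = stream.timestamps()
    quats = (
        list(quaternions) if quaternions is not None
        else estimate_orientation(stream, method)
    )
    angles = np.array(
        [approach_angle(relative_orientation(reference, q)) for q in quats]
    )
    out: list[TackleEvent] = []
    for i, ev in enumerate(events):
        peak = ev.peak_index
        if peak is None:
            peak = int(np.argmin(np.abs(t - (ev.start_ms + ev.end_ms) / 2)))
        t_peak = t[peak]
        win = (t >= t_peak - contact_window_ms) & (t <= t_peak + contact_window_ms)
        mean_angle = float(np.mean(angles[win]))
        shoulder = shoulders[i] if shoulders is not None else ev.shoulder
        out.append(
            TackleEvent(
                start_ms=ev.start_ms,
                end_ms=ev.end_ms,
                peak_accel=ev.peak_accel,
                approach_angle_deg=mean_angle,
                approach_angle_instant_deg=float(angles[peak]),
                shoulder=shoulder,
                label=classify(mean_angle, config),
                peak_index=peak,
            )
        )
    return out


def summarize_session(events: Sequence[TackleEvent]) -> dict[str, Any]:
    """Per-side and overall SAFE/UNSAFE counts plus angle statistics."""
    summary: dict[str, Any] = {
        "total": len(events),
        "safe": sum(1 for e in events if e.label is Label.SAFE),
        "unsafe": sum(1 for e in events if e.label is Label.UNSAFE),
        "by_shoulder": {},
        "angle_stats": None,
    }
    for side in Shoulder:
        side_events = [e for e in events if e.shoulder is side]
        if side_events:
            summary["by_shoulder"][side.value] = {
                "total": len(side_events),
                "safe": sum(1 for e in side_events if e.label is Label.SAFE),
                "unsafe": sum(1 for e in side_events if e.label is Label.UNSAFE),
            }
    angles = [e.approach_angle_deg for e in events if math.isfinite(e.approach_angle_deg)]
    if angles:
        arr = np.array(angles)
        summary["angle_stats"] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    return summary
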
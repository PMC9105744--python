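"""Shimmer-style IMU log and coaching-session input/output.

A Shimmer3 9-DoF wearable logs one record per sample with 38 named
fields: two timestamps, raw and calibrated channels for the low-noise
accelerometer (m/s^2), wide-range accelerometer (m/s^2), gyroscope
(deg/s) and magnetometer (cgs flux), pressure and temperature, plus the
axis-angle and quaternion orientation computed by the onboard fusion
processor.  This module parses such logs from delimited text (readings
as rows or as columns, auto-detected), validates them, orders them by
calibrated timestamp, serialises coaching sessions to a versioned JSON
format, and replays streams in timestamp order.

Numbers are kept at full parsed precision; the two-decimal rounding seen
in printed logs is a display concern only.  Thousands separators and the
typographic minus sign (U+2212) are accepted on input.
"""

from __future__ import annotations

import io
import json
import math
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import IO, Any, Iterator

import numpy as np
import pandas as pd

from . import orientation as _ori

#: device ticks per second of the raw timestamp clock.  Inferred from
#: logged data (6400 ticks per 195.31 ms sample interval); the device
#: documentation does not state it, so it stays configurable.
DEFAULT_TICKS_PER_SECOND = 32768.0

FORMAT_VERSION = "1"


class SchemaError(ValueError):
    """A required field is missing or a document violates the schema."""


class ParseError(ValueError):
    """A cell or document could not be parsed as the expected type."""


class OrderingError(ValueError):
    """Timestamps are duplicated or otherwise cannot define an order."""


# Canonical log vocabulary -> attribute name, in canonical column order.
COLUMN_TO_ATTR: dict[str, str] = {
    "Timestamp_RAW": "timestamp_raw",
    "Timestamp_CAL": "timestamp_cal",
    "Low_Noise_Accelerometer_X_RAW": "ln_accel_x_raw",
    "Low_Noise_Accelerometer_X_CAL": "ln_accel_x_cal",
    "Low_Noise_Accelerometer_Y_RAW": "ln_accel_y_raw",
    "Low_Noise_Accelerometer_Y_CAL": "ln_accel_y_cal",
    "Low_Noise_Accelerometer_Z_RAW": "ln_accel_z_raw",
    "Low_Noise_Accelerometer_Z_CAL": "ln_accel_z_cal",
    "Wide_Range_Accelerometer_X_RAW": "wr_accel_x_raw",
    "Wide_Range_Accelerometer_X_CAL": "wr_accel_x_cal",
    "Wide_Range_Accelerometer_Y_RAW": "wr_accel_y_raw",
    "Wide_Range_Accelerometer_Y_CAL": "wr_accel_y_cal",
    "Wide_Range_Accelerometer_Z_RAW": "wr_accel_z_raw",
    "Wide_Range_Accelerometer_Z_CAL": "wr_accel_z_cal",
    "Gyroscope_X_RAW": "gyro_x_raw",
    "Gyroscope_X_CAL": "gyro_x_cal",
    "Gyroscope_Y_RAW": "gyro_y_raw",
    "Gyroscope_Y_CAL": "gyro_y_cal",
    "Gyroscope_Z_RAW": "gyro_z_raw",
    "Gyroscope_Z_CAL": "gyro_z_cal",
    "Magnetometer_X_RAW": "mag_x_raw",
    "Magnetometer_X_CAL": "mag_x_cal",
    "Magnetometer_Y_RAW": "mag_y_raw",
    "Magnetometer_Y_CAL": "mag_y_cal",
    "Magnetometer_Z_RAW": "mag_z_raw",
    "Magnetometer_Z_CAL": "mag_z_cal",
    "Pressure_RAW": "pressure_raw",
    "Pressure_CAL": "pressure_cal",
    "Temperature_RAW": "temperature_raw",
    "Temperature_CAL": "temperature_cal",
    "Axis_Angle_A_CAL": "axis_angle_a_cal",
    "Axis_Angle_X_CAL": "axis_angle_x_cal",
    "Axis_Angle_Y_CAL": "axis_angle_y_cal",
    "Axis_Angle_Z_CAL": "axis_angle_z_cal",
    "Quaternion_0_CAL": "quat_0_cal",
    "Quaternion_1_CAL": "quat_1_cal",
    "Quaternion_2_CAL": "quat_2_cal",
    "Quaternion_3_CAL": "quat_3_cal",
}
ATTR_TO_COLUMN = {v: k for k, v in COLUMN_TO_ATTR.items()}
N_FIELDS = len(COLUMN_TO_ATTR)  # 38

#: |quaternion norm - 1| allowed for logged onboard quaternions; wide
#: enough to absorb two-decimal rounding of the stored components.
QUAT_NORM_TOL = 0.02
#: |axis norm - 1| allowed for the logged rotation axis, checked only
#: when the rotation angle exceeds AXIS_CHECK_MIN_ANGLE (below that the
#: axis direction is numerically unreliable).
AXIS_NORM_TOL = 0.05
AXIS_CHECK_MIN_ANGLE = 0.05  # rad


@dataclass
class ImuReading:
    """One timestamped 38-field sensor sample.

    ``timestamp_raw`` is in device ticks, ``timestamp_cal`` in
    milliseconds.  Calibrated accelerometers are m/s^2, the gyroscope
    deg/s, the magnetometer cgs flux.  ``axis_angle_a_cal`` is radians
    with ``axis_angle_{x,y,z}_cal`` the unit rotation axis, and
    ``quat_{0..3}_cal`` is the onboard quaternion with component 0 the
    scalar (w) part.
    """

    timestamp_raw: float
    timestamp_cal: float
    ln_accel_x_raw: float
    ln_accel_x_cal: float
    ln_accel_y_raw: float
    ln_accel_y_cal: float
    ln_accel_z_raw: float
    ln_accel_z_cal: float
    wr_accel_x_raw: float
    wr_accel_x_cal: float
    wr_accel_y_raw: float
    wr_accel_y_cal: float
    wr_accel_z_raw: float
    wr_accel_z_cal: float
    gyro_x_raw: float
    gyro_x_cal: float
    gyro_y_raw: float
    gyro_y_cal: float
    gyro_z_raw: float
    gyro_z_cal: float
    mag_x_raw: float
    mag_x_cal: float
    mag_y_raw: float
    mag_y_cal: float
    mag_z_raw: float
    mag_z_cal: float
    pressure_raw: float
    pressure_cal: float
    temperature_raw: float
    temperature_cal: float
    axis_angle_a_cal: float
    axis_angle_x_cal: float
    axis_angle_y_cal: float
    axis_angle_z_cal: float
    quat_0_cal: float
    quat_1_cal: float
    quat_2_cal: float
    quat_3_cal: float

    def quaternion(self) -> "_ori.Quaternion":
        """The onboard quaternion of this sample (not normalised)."""
        return _ori.Quaternion(
            self.quat_0_cal, self.quat_1_cal, self.quat_2_cal, self.quat_3_cal
        )

    def wr_accel_magnitude(self) -> float:
        """Magnitude of the calibrated wide-range acceleration, m/s^2."""
        return math.sqrt(
            self.wr_accel_x_cal**2 + self.wr_accel_y_cal**2 + self.wr_accel_z_cal**2
        )

    def validate(self) -> None:
        qnorm = math.sqrt(
            self.quat_0_cal**2
            + self.quat_1_cal**2
            + self.quat_2_cal**2
            + self.quat_3_cal**2
        )
        if abs(qnorm - 1.0) > QUAT_NORM_TOL:
            raise SchemaError(
                f"onboard quaternion norm {qnorm:.4f} deviates from 1 by more "
                f"than {QUAT_NORM_TOL} at timestamp_cal={self.timestamp_cal}"
            )
        if self.axis_angle_a_cal > AXIS_CHECK_MIN_ANGLE:
            anorm = math.sqrt(
                self.axis_angle_x_cal**2
                + self.axis_angle_y_cal**2
                + self.axis_angle_z_cal**2
            )
            if abs(anorm - 1.0) > AXIS_NORM_TOL:
                raise SchemaError(
                    f"axis-angle axis norm {anorm:.4f} deviates from 1 by more "
                    f"than {AXIS_NORM_TOL} at timestamp_cal={self.timestamp_cal}"
                )


@dataclass
class ImuStream:
    """An ordered sequence of :class:`ImuReading` from one recording.

    ``sample_interval_ticks`` is the raw-clock spacing between
    consecutive samples; ``irregular`` is set when that spacing varies
    by more than one tick across the stream.
    """

    readings: list[ImuReading]
    sample_interval_ticks: float | None = None
    irregular: bool = False
    ticks_per_second: float = DEFAULT_TICKS_PER_SECOND
    meta: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.readings)

    def __iter__(self) -> Iterator[ImuReading]:
        return iter(self.readings)

    def column(self, attr: str) -> np.ndarray:
        """Return one field across all readings as a float array."""
        return np.array([getattr(r, attr) for r in self.readings], dtype=float)

    def timestamps(self) -> np.ndarray:
        return self.column("timestamp_cal")

    def to_frame(self) -> pd.DataFrame:
        """All readings as a DataFrame with canonical column names."""
        data = {
            col: [getattr(r, attr) for r in self.readings]
            for col, attr in COLUMN_TO_ATTR.items()
        }
        return pd.DataFrame(data)

    def onboard_quaternions(self) -> list["_ori.Quaternion"]:
        return [r.quaternion() for r in self.readings]


def _read_text(source: str | Path | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        return source  # literal document text, not a path
    path = Path(source)
    if path.exists():
        return path.read_text(encoding="utf-8")
    raise FileNotFoundError(source)


def _normalise_text(text: str) -> str:
    # U+2212 (minus sign) appears in typeset logs; parse it as '-'.
    return text.replace("−", "-")


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def parse_shimmer_table(
    source: str | Path | IO[str],
    *,
    delimiter: str | None = None,
    ticks_per_second: float = DEFAULT_TICKS_PER_SECOND,
) -> ImuStream:
    """Parse a delimited 38-field IMU log into an ordered :class:`ImuStream`.

    Both layouts are accepted and auto-detected: one *row* per reading
    with a header naming the fields, or one *column* per reading with
    field names in the first column (the layout printed device dumps
    use).  Readings are returned ordered by ``timestamp_cal``.

    Raises :class:`SchemaError` if a mandatory field is absent,
    :class:`ParseError` for non-numeric cells and :class:`OrderingError`
    for duplicated calibrated timestamps.
    """
    text = _normalise_text(_read_text(source))
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty document: no header found")
    delim = delimiter or _detect_delimiter(lines[0])

    first_tokens = [t.strip() for t in lines[0].split(delim)]
    if "Timestamp_RAW" in first_tokens:
        readings_as_rows = True
    elif any(ln.split(delim)[0].strip() == "Timestamp_RAW" for ln in lines):
        readings_as_rows = False
    else:
        raise SchemaError("missing mandatory field: Timestamp_RAW")

    buf = io.StringIO(text)
    if readings_as_rows:
        df = pd.read_csv(buf, sep=delim, thousands=",", skipinitialspace=True,
                         float_precision="round_trip")
        df.columns = [str(c).strip() for c in df.columns]
    else:
        df = pd.read_csv(
            buf, sep=delim, thousands=",", index_col=0, skipinitialspace=True,
            float_precision="round_trip",
        )
        df.index = [str(i).strip() for i in df.index]
        df = df.T

    missing = [c for c in COLUMN_TO_ATTR if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory field: {missing[0]}")
    df = df[list(COLUMN_TO_ATTR)]

    for col in df.columns:
        try:
            df[col] = pd.to_numeric(
                df[col].astype(str).str.replace(",", "", regex=False)
                if df[col].dtype == object
                else df[col],
                errors="raise",
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric cell in field {col!r}: {exc}") from None
    if df[list(COLUMN_TO_ATTR)].isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise ParseError(f"missing value in field {bad!r}")

    ts = df["Timestamp_CAL"].to_numpy(dtype=float)
    if len(np.unique(ts)) != len(ts):
        dup = float(pd.Series(ts)[pd.Series(ts).duplicated()].iloc[0])
        raise OrderingError(f"duplicated Timestamp_CAL value {dup}")
    df = df.sort_values("Timestamp_CAL", kind="stable").reset_index(drop=True)

    readings = [
        ImuReading(**{attr: float(row[col]) for col, attr in COLUMN_TO_ATTR.items()})
        for _, row in df.iterrows()
    ]
    for r in readings:
        r.validate()

    interval: float | None = None
    irregular = False
    if len(readings) >= 2:
        diffs = np.diff([r.timestamp_raw for r in readings])
        interval = float(np.median(diffs))
        irregular = bool(np.any(np.abs(diffs - interval) > 1.0))
    return ImuStream(
        readings=readings,
        sample_interval_ticks=interval,
        irregular=irregular,
        ticks_per_second=ticks_per_second,
    )


def write_shimmer_table(
    stream: ImuStream,
    sink: str | Path | IO[str] | None = None,
    *,
    orientation: str = "rows",
    delimiter: str = "\t",
) -> str:
    """Serialise a stream back to delimited text at full precision.

    ``orientation`` is ``"rows"`` (one reading per row, header names the
    fields) or ``"columns"`` (the printed-dump layout, one reading per
    column).  Returns the text; also writes it when ``sink`` is given.
    """
    # repr round-trips float64 exactly; to_csv's default writer does not
    df = stream.to_frame().map(repr)
    if orientation == "rows":
        text = df.to_csv(sep=delimiter, index=False)
    elif orientation == "columns":
        tdf = df.T
        tdf.columns = [f"Reading {i + 1}" for i in range(len(df))]
        text = tdf.to_csv(sep=delimiter, index=True, index_label="")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)  # type: ignore[union-attr]
        else:
            Path(sink).write_text(text, encoding="utf-8")
    return text


def order_replay(
    stream: ImuStream, speed: float | None = None
) -> Iterator[tuple[float, ImuReading]]:
    """Yield ``(timestamp_cal, reading)`` in strictly increasing time order.

    When ``speed`` is a positive number the generator sleeps between
    samples so the replay runs at ``speed`` times real time; any other
    value (including 0 and None) yields without delay.  The speed factor
    scales inter-sample delays only — it never reorders.
    """
    ordered = sorted(stream.readings, key=lambda r: r.timestamp_cal)
    prev_t: float | None = None
    for r in ordered:
        if speed is not None and speed > 0 and prev_t is not None:
            time.sleep((r.timestamp_cal - prev_t) / 1000.0 / speed)
        prev_t = r.timestamp_cal
        yield r.timestamp_cal, r


# ---------------------------------------------------------------------------
# Session serialisation
# ---------------------------------------------------------------------------


@dataclass
class SessionRecord:
    """A participant's analysed coaching session: ordered tackle events
    plus the calibration reference they were measured against."""

    participant_id: str
    events: list[Any]  # list[tackle_analysis.TackleEvent]
    reference: Any | None = None  # calibration.ReferencePose
    created: str = ""

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise SchemaError("participant_id must be a non-empty string")
        starts = [e.start_ms for e in self.events]
        if starts != sorted(starts):
            raise OrderingError("session events must be ordered by start time")


def write_session(
    session: SessionRecord, sink: str | Path | IO[str] | None = None
) -> str:
    """Serialise a session to versioned JSON (floats at full precision)."""
    doc: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "participant_id": session.participant_id,
        "created": session.created,
        "reference": None,
        "events": [e.to_dict() for e in session.events],
    }
    if session.reference is not None:
        doc["reference"] = session.reference.to_dict()
    text = json.dumps(doc, indent=2)
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)  # type: ignore[union-attr]
        else:
            Path(sink).write_text(text, encoding="utf-8")
    return text


def read_session(source: str | Path | IO[str]) -> SessionRecord:
    """Parse a session document; inverse of :func:`write_session`."""
    from .calibration import ReferencePose
    from .tackle_analysis import TackleEvent

    text = _read_text(source)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed session document at $: {exc}") from None
    if not isinstance(doc, dict):
        raise SchemaError("session document must be a JSON object at $")
    if "participant_id" not in doc or not doc["participant_id"]:
        raise SchemaError("missing required field at $.participant_id")
    if "events" not in doc or not isinstance(doc["events"], list):
        raise SchemaError("missing required field at $.events")
    events = []
    for i, ev in enumerate(doc["events"]):
        try:
            events.append(TackleEvent.from_dict(ev))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed event at $.events[{i}]: {exc}") from None
    reference = None
    if doc.get("reference") is not None:
        try:
            reference = ReferencePose.from_dict(doc["reference"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed reference at $.reference: {exc}") from None
    return SessionRecord(
        participant_id=str(doc["participant_id"]),
        events=events,
        reference=reference,
        created=str(doc.get("created", "")),
    )


def packaged_sample_path() -> Path:
    """Path to the packaged four-reading sample log (printed-dump layout)."""
    return Path(__file__).parent / "data" / "table1_sample.tsv"


def load_sample_stream() -> ImuStream:
    """Parse the packaged four-reading sample log."""
    return parse_shimmer_table(packaged_sample_path())


assert len(dc_fields(ImuReading)) == N_FIELDS
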
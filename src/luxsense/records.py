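"""Domain types and I/O for bubble-tube interaction logs.

Two kinds of session logs exist, one per operating mode of the stimulation
device:

* **CCM** (child control mode) — the child drives the bubble tube through a
  control panel; each record is one chosen stimulus (color, binarized
  illumination level, dwell duration in seconds).
* **SCM** (system control mode) — the device cycles stimuli automatically
  every few seconds; each record is one presented stimulus together with the
  child's valence-coded emotional response (positive/negative).

Logs are plain CSV with a header row.  CCM columns are
``date_time,color,illumination,duration_s[,session]``; SCM columns are
``date_time,color,illumination,response[,session]`` where ``response`` is
``P``/``N`` or one of the six raw facial-emotion words (mapped to valence at
parse time).  The optional 1-based ``session`` column groups records into
sessions; without it the whole file is one session.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence, TextIO, Union

__all__ = [
    "Color",
    "Illumination",
    "Valence",
    "Emotion",
    "Mode",
    "CCMRecord",
    "SCMRecord",
    "ChildLog",
    "LogParseError",
    "valence_of",
    "binarize_illumination",
    "illumination_at_distance",
    "parse_log",
    "write_log",
    "read_log",
]


class Color(str, Enum):
    """The five stimulus colors the bubble tube can generate."""

    RED = "R"
    GREEN = "G"
    BLUE = "B"
    YELLOW = "Y"
    WHITE = "W"


class Illumination(str, Enum):
    """Binarized illumination class: below vs. at-or-above 100 lux at 1 m."""

    LOW = "LI"
    HIGH = "HI"


class Valence(str, Enum):
    """Binary emotional-response coding."""

    POSITIVE = "P"
    NEGATIVE = "N"


class Emotion(str, Enum):
    """The six facial-emotion classes produced by the emotion recognizer."""

    JOY = "joy"
    SURPRISE = "surprise"
    ANGER = "anger"
    FEAR = "fear"
    SADNESS = "sadness"
    NEUTRALITY = "neutrality"


class Mode(str, Enum):
    """Operating mode of the stimulation device."""

    CCM = "CCM"
    SCM = "SCM"


#: Emotions coded as positive; the remaining four (anger, fear, sadness,
#: neutrality) are coded negative.  Neutrality counts as negative because it
#: reflects a lack of positive engagement with the stimulus.
POSITIVE_EMOTIONS = frozenset({Emotion.JOY, Emotion.SURPRISE})


def valence_of(label: Union[Emotion, str]) -> Valence:
    """Map a facial-emotion label to its binary valence.

    Joy and surprise map to :attr:`Valence.POSITIVE`; anger, fear, sadness and
    neutrality map to :attr:`Valence.NEGATIVE`.

    Raises
    ------
    ValueError
        If ``label`` is not one of the six emotion classes.
    """
    if isinstance(label, str) and not isinstance(label, Emotion):
        try:
            label = Emotion(label.strip().lower())
        except ValueError:
            raise ValueError(f"unknown emotion label: {label!r}") from None
    return Valence.POSITIVE if label in POSITIVE_EMOTIONS else Valence.NEGATIVE


def binarize_illumination(lux: float) -> Illumination:
    """Binarize an illuminance (lux, measured at 1 m) into LI/HI.

    Below 100 lux is low illumination (LI); 100 lux and above is high (HI).
    The 100-lux boundary itself is assigned to HI so the map is total.

    Raises
    ------
    ValueError
        If ``lux`` is not strictly positive.
    """
    if lux <= 0:
        raise ValueError(f"illuminance must be positive, got {lux}")
    return Illumination.LOW if lux < 100 else Illumination.HIGH


def illumination_at_distance(lux_at_1m: float, distance_m: float) -> float:
    """Illuminance at ``distance_m`` meters given the value measured at 1 m.

    Point-source inverse-square law: intensity falls with the square of the
    distance, so at half a meter the illumination is four times the 1-m value.

    Raises
    ------
    ValueError
        If ``distance_m`` is not strictly positive.
    """
    if distance_m <= 0:
        raise ValueError(f"distance must be positive, got {distance_m}")
    return lux_at_1m / distance_m**2


@dataclass(frozen=True)
class CCMRecord:
    """One child-chosen stimulus: color, illumination class, dwell seconds."""

    timestamp: datetime
    color: Color
    illumination: Illumination
    duration_s: int

    def __post_init__(self) -> None:
        if not isinstance(self.duration_s, int) or isinstance(self.duration_s, bool):
            raise TypeError("duration_s must be an integer number of seconds")
        if self.duration_s < 0:
            raise ValueError(f"duration_s must be >= 0, got {self.duration_s}")


@dataclass(frozen=True)
class SCMRecord:
    """One system-generated stimulus with the child's valence-coded response."""

    timestamp: datetime
    color: Color
    illumination: Illumination
    response: Valence


_RECORD_TYPE = {Mode.CCM: CCMRecord, Mode.SCM: SCMRecord}


@dataclass(frozen=True)
class ChildLog:
    """All sessions of one child in one mode.

    ``sessions`` is an ordered tuple of sessions, each a tuple of records of
    the mode's record type.  The field protocol runs three sessions per mode,
    but any count >= 1 is accepted.
    """

    child_id: str
    mode: Mode
    sessions: tuple[tuple, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sessions", tuple(tuple(s) for s in self.sessions))
        if len(self.sessions) < 1:
            raise ValueError("a ChildLog needs at least one session")
        want = _RECORD_TYPE[Mode(self.mode)]
        for session in self.sessions:
            for rec in session:
                if not isinstance(rec, want):
                    raise TypeError(
                        f"{self.mode.value} log contains a {type(rec).__name__}"
                    )

    @property
    def records(self) -> tuple:
        """All records pooled across sessions, in session order."""
        return tuple(r for s in self.sessions for r in s)

    @property
    def n_records(self) -> int:
        return sum(len(s) for s in self.sessions)

    def __iter__(self) -> Iterator:
        return iter(self.records)


class LogParseError(ValueError):
    """A malformed log row; carries the 1-based data-row number and field."""

    def __init__(self, row: int, fieldname: str, message: str):
        self.row = row
        self.fieldname = fieldname
        super().__init__(f"row {row}, field {fieldname!r}: {message}")


_TS_FORMATS = ("%Y-%m-%d %H:%M:%S", "%Y-%m-%d %H:%M")


def _parse_timestamp(text: str, row: int) -> datetime:
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(text.strip(), fmt)
        except ValueError:
            continue
    raise LogParseError(row, "date_time", f"malformed timestamp {text!r}")


def _parse_enum(enum_cls, text: str, row: int, fieldname: str):
    try:
        return enum_cls(text.strip())
    except ValueError:
        raise LogParseError(
            row, fieldname, f"unknown {fieldname} code {text.strip()!r}"
        ) from None


_REQUIRED_COLS = {
    Mode.CCM: ("date_time", "color", "illumination", "duration_s"),
    Mode.SCM: ("date_time", "color", "illumination", "response"),
}


def parse_log(
    source: Union[str, TextIO], mode: Union[Mode, str], child_id: str = ""
) -> ChildLog:
    """Parse a CSV interaction log into a :class:`ChildLog`.

    ``source`` may be CSV text or an open text stream.  Timestamps are
    accepted at minute or second precision (minutes are stored padded with
    ``:00``).  SCM ``response`` cells may hold ``P``/``N`` or a raw
    six-emotion word, which is mapped through :func:`valence_of`.

    Rows are grouped into sessions by the optional 1-based ``session``
    column; when it is absent the whole file is a single session.  Records
    within a session must be chronologically non-decreasing.

    Raises
    ------
    LogParseError
        Naming the offending 1-based data row and field, for any enum
        violation, negative duration, malformed timestamp, bad session
        number, or out-of-order timestamp.
    ValueError
        If the header is missing required columns.
    """
    mode = Mode(mode)
    stream = io.StringIO(source) if isinstance(source, str) else source
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        raise ValueError("log has no header row")
    header = [h.strip() for h in reader.fieldnames]
    missing = [c for c in _REQUIRED_COLS[mode] if c not in header]
    if missing:
        raise ValueError(f"{mode.value} log header is missing columns: {missing}")
    has_session = "session" in header

    by_session: dict[int, list] = {}
    for row_no, row in enumerate(reader, start=1):
        ts = _parse_timestamp(row["date_time"] or "", row_no)
        color = _parse_enum(Color, row["color"] or "", row_no, "color")
        illum = _parse_enum(Illumination, row["illumination"] or "", row_no, "illumination")
        if mode is Mode.CCM:
            raw = (row["duration_s"] or "").strip()
            try:
                duration = int(raw)
            except ValueError:
                raise LogParseError(
                    row_no, "duration_s", f"not an integer: {raw!r}"
                ) from None
            if duration < 0:
                raise LogParseError(row_no, "duration_s", f"negative duration {duration}")
            rec = CCMRecord(ts, color, illum, duration)
        else:
            raw = (row["response"] or "").strip()
            if raw in ("P", "N"):
                response = Valence(raw)
            else:
                try:
                    response = valence_of(raw)
                except ValueError:
                    raise LogParseError(
                        row_no, "response", f"unknown response code {raw!r}"
                    ) from None
            rec = SCMRecord(ts, color, illum, response)

        if has_session:
            raw = (row.get("session") or "").strip()
            try:
                session_no = int(raw)
            except ValueError:
                raise LogParseError(row_no, "session", f"not an integer: {raw!r}") from None
            if session_no < 1:
                raise LogParseError(row_no, "session", f"session must be >= 1, got {session_no}")
        else:
            session_no = 1
        bucket = by_session.setdefault(session_no, [])
        if bucket and bucket[-1].timestamp > ts:
            raise LogParseError(
                row_no, "date_time", "timestamps within a session must be non-decreasing"
            )
        bucket.append(rec)

    n_sessions = max(by_session) if by_session else 1
    sessions = tuple(tuple(by_session.get(i, ())) for i in range(1, n_sessions + 1))
    return ChildLog(child_id=child_id, mode=mode, sessions=sessions)


def write_log(log: ChildLog) -> str:
    """Serialize a :class:`ChildLog` back to CSV text.

    Inverse of :func:`parse_log`: parsing the output with the same mode
    reproduces the log.  The ``session`` column is emitted only for
    multi-session logs.
    """
    mode = Mode(log.mode)
    cols = list(_REQUIRED_COLS[mode])
    multi = len(log.sessions) > 1
    if multi:
        cols.append("session")
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(cols)
    for session_no, session in enumerate(log.sessions, start=1):
        for rec in session:
            row = [
                rec.timestamp.strftime("%Y-%m-%d %H:%M:%S"),
                rec.color.value,
                rec.illumination.value,
            ]
            if mode is Mode.CCM:
                row.append(str(rec.duration_s))
            else:
                row.append(rec.response.value)
            if multi:
                row.append(str(session_no))
            writer.writerow(row)
    return out.getvalue()


def read_log(path: Union[str, Path], mode: Union[Mode, str], child_id: str = "") -> ChildLog:
    """Read a log CSV file; ``child_id`` defaults to the file stem."""
    path = Path(path)
    if not child_id:
        child_id = path.stem
    with open(path, newline="", encoding="utf-8") as fh:
        return parse_log(fh, mode, child_id=child_id)
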
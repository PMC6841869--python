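"""Modality-log data model: events, sequences, exams, billing records.

No public format exists for MRI scanner logs, so the package defines its
own JSON-lines event dialect (one event per line) and a small CSV dialect
for per-exam billing records.  Raw events are assembled into
:class:`ExamInstance` objects: everything from a subject registration on
the host computer up to the end of the last MR sequence before the next
registration belongs to one exam.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import IO, Iterable, Mapping, Optional, Sequence

__all__ = [
    "EVENT_KINDS",
    "TECHNIQUES",
    "ORIENTATIONS",
    "LogEvent",
    "SequenceRecord",
    "ExamInstance",
    "BillingRecord",
    "Reject",
    "EventLog",
    "AssemblyResult",
    "MergeResult",
    "MergeAmbiguityError",
    "read_events",
    "write_events",
    "assemble_exams",
    "read_billing",
    "write_billing",
    "merge_billing",
    "write_rejects",
]

EVENT_KINDS = frozenset(
    {"registration", "sequence_start", "sequence_end", "table_move", "contrast_injection"}
)
TECHNIQUES = frozenset(
    {"se", "tse", "gre", "vibe", "haste", "ep2d", "trufi", "tirm", "other"}
)
ORIENTATIONS = frozenset({"tra", "sag", "cor", "oblique"})
DIMENSIONALITIES = frozenset({"2d", "3d"})

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def _parse_ts(value: str) -> datetime:
    return datetime.strptime(value, _TS_FMT)


def _fmt_ts(value: datetime) -> str:
    return value.strftime(_TS_FMT)


@dataclass(frozen=True)
class LogEvent:
    """A single modality log event.

    ``payload`` is kind specific: sequence events carry a
    :class:`SequenceRecord` fragment, ``table_move`` carries
    ``position_mm``, ``registration`` carries ``subject_token`` and
    ``approximate_age_years``.
    """

    event_kind: str
    timestamp: datetime
    scanner_id: str
    payload: Mapping[str, object] = field(default_factory=dict)

    def to_json_obj(self) -> dict:
        return {
            "event_kind": self.event_kind,
            "timestamp": _fmt_ts(self.timestamp),
            "scanner_id": self.scanner_id,
            "payload": dict(self.payload),
        }


@dataclass(frozen=True)
class SequenceRecord:
    """One executed MR sequence with timing and acquisition parameters."""

    raw_name: str
    start_time: datetime
    end_time: datetime
    tr_ms: float
    te_ms: float
    ti_ms: Optional[float] = None
    technique: str = "other"
    dimensionality: str = "2d"
    orientation: str = "tra"
    fat_saturation: bool = False
    breath_hold: bool = False
    b_values: tuple = ()
    fov_mm: float = 300.0
    slice_thickness_mm: float = 4.0
    coil_ids: frozenset = frozenset()
    table_position_mm: float = 0.0

    def __post_init__(self):
        if self.end_time < self.start_time:
            raise ValueError(
                f"sequence {self.raw_name!r}: end_time precedes start_time"
            )
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def duration_s(self) -> float:
        return (self.end_time - self.start_time).total_seconds()


@dataclass
class ExamInstance:
    """One MRI exam: registration context plus the assembled sequences.

    The exam span runs from subject registration to the end of the last
    sequence.  ``labelset`` is absent (None) at prediction time.
    """

    exam_id: str
    registration_time: datetime
    sequences: list = field(default_factory=list)
    table_positions: list = field(default_factory=list)  # (datetime, position_mm)
    contrast_given: bool = False
    approximate_age_years: float = 0.0
    scanner_id: str = ""
    labelset: Optional[object] = None  # labels.Labelset once merged
    aborted: bool = False
    no_billing_match: bool = False

    @property
    def end_time(self) -> datetime:
        if self.sequences:
            return max(s.end_time for s in self.sequences)
        return self.registration_time

    @property
    def span_s(self) -> float:
        return (self.end_time - self.registration_time).total_seconds()


@dataclass(frozen=True)
class BillingRecord:
    """One charged billing-code entry, keyed by exam id or timestamp."""

    code_id: str
    count: int
    exam_id: Optional[str] = None
    timestamp: Optional[datetime] = None

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("billing count must be >= 1")
        if self.exam_id is None and self.timestamp is None:
            raise ValueError("billing record needs an exam_id or a timestamp key")


@dataclass(frozen=True)
class Reject:
    line_no: int
    reason: str


@dataclass
class EventLog:
    events: list
    rejects: list


@dataclass
class AssemblyResult:
    exams: list
    rejects: list


@dataclass
class MergeResult:
    exams: list
    unmatched: list  # BillingRecord with no exam


class MergeAmbiguityError(ValueError):
    """A timestamp-keyed billing record matches more than one exam."""


# ---------------------------------------------------------------------------
# Event file dialect

_SEQ_PAYLOAD_KEYS = {
    "raw_name", "tr_ms", "te_ms", "ti_ms", "technique", "dimensionality",
    "orientation", "fat_saturation", "breath_hold", "b_values", "fov_mm",
    "slice_thickness_mm", "coil_ids", "table_position_mm",
}


def _validate_payload(kind: str, payload: Mapping[str, object]) -> Optional[str]:
    """Return a reject reason if the payload is inconsistent with the kind."""
    if kind == "registration":
        if "subject_token" not in payload:
            return "registration payload missing subject_token"
    elif kind == "sequence_start":
        missing = {"raw_name", "tr_ms", "te_ms"} - set(payload)
        if missing:
            return f"sequence_start payload missing {sorted(missing)}"
        tech = payload.get("technique", "other")
        if tech not in TECHNIQUES:
            return f"unknown technique {tech!r}"
    elif kind == "sequence_end":
        if "raw_name" not in payload:
            return "sequence_end payload missing raw_name"
    elif kind == "table_move":
        if "position_mm" not in payload:
            return "table_move payload missing position_mm"
    elif kind == "contrast_injection":
        pass
    return None


def read_events(stream: IO[str] | Iterable[str]) -> EventLog:
    """Read the JSON-lines event dialect.

    Malformed lines are collected into the rejects report rather than
    silently dropped; an empty stream yields an empty (valid) log.
    Events are returned sorted by timestamp.
    """
    events: list[LogEvent] = []
    rejects: list[Reject] = []
    for line_no, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            rejects.append(Reject(line_no, f"invalid JSON: {exc.msg}"))
            continue
        kind = obj.get("event_kind")
        if kind not in EVENT_KINDS:
            rejects.append(Reject(line_no, f"unknown event_kind {kind!r}"))
            continue
        try:
            ts = _parse_ts(obj["timestamp"])
        except (KeyError, TypeError, ValueError):
            rejects.append(
                Reject(line_no, f"unparseable timestamp {obj.get('timestamp')!r}")
            )
            continue
        payload = obj.get("payload", {})
        if not isinstance(payload, dict):
            rejects.append(Reject(line_no, "payload is not an object"))
            continue
        reason = _validate_payload(kind, payload)
        if reason is not None:
            rejects.append(Reject(line_no, reason))
            continue
        events.append(
            LogEvent(kind, ts, str(obj.get("scanner_id", "")), payload)
        )
    events.sort(key=lambda e: e.timestamp)
    return EventLog(events=events, rejects=rejects)


def write_events(events: Sequence[LogEvent], stream: IO[str]) -> None:
    """Write events as JSON lines (sorted keys, so output is reproducible)."""
    for ev in events:
        stream.write(json.dumps(ev.to_json_obj(), sort_keys=True))
        stream.write("\n")


def write_rejects(rejects: Sequence[Reject], stream: IO[str]) -> None:
    writer = csv.writer(stream)
    writer.writerow(["line_no", "reason"])
    for r in rejects:
        writer.writerow([r.line_no, r.reason])


# ---------------------------------------------------------------------------
# Exam assembly


def _sequence_from_payload(
    start: LogEvent, end_time: datetime
) -> SequenceRecord:
    p = start.payload
    b_values = tuple(float(b) for b in p.get("b_values", []) or [])
    ti = p.get("ti_ms")
    return SequenceRecord(
        raw_name=str(p["raw_name"]),
        start_time=start.timestamp,
        end_time=end_time,
        tr_ms=float(p["tr_ms"]),
        te_ms=float(p["te_ms"]),
        ti_ms=None if ti is None else float(ti),
        technique=str(p.get("technique", "other")),
        dimensionality=str(p.get("dimensionality", "2d")),
        orientation=str(p.get("orientation", "tra")),
        fat_saturation=bool(p.get("fat_saturation", False)),
        breath_hold=bool(p.get("breath_hold", False)),
        b_values=b_values,
        fov_mm=float(p.get("fov_mm", 300.0)),
        slice_thickness_mm=float(p.get("slice_thickness_mm", 4.0)),
        coil_ids=frozenset(str(c) for c in p.get("coil_ids", []) or []),
        table_position_mm=float(p.get("table_position_mm", 0.0)),
    )


def assemble_exams(events: Sequence[LogEvent]) -> AssemblyResult:
    """Partition timestamp-ordered events into exams, per scanner.

    Each registration opens a new exam; all later events up to (and
    including, on timestamp ties) the last ``sequence_end`` before the
    next registration belong to it.  Exams that never complete a
    sequence are kept but flagged ``aborted``.  A ``sequence_end``
    without a matching open ``sequence_start`` rejects that sequence but
    keeps the exam; events before any registration go to the rejects
    report.
    """
    rejects: list[Reject] = []
    exams: list[ExamInstance] = []

    # Closed right end: a sequence_end sharing its timestamp with the next
    # registration belongs to the earlier exam, so registrations sort after
    # other kinds on timestamp ties.
    events = sorted(
        events,
        key=lambda e: (e.timestamp, 1 if e.event_kind == "registration" else 0),
    )

    by_scanner: dict[str, list[tuple[int, LogEvent]]] = {}
    for idx, ev in enumerate(events):
        by_scanner.setdefault(ev.scanner_id, []).append((idx, ev))

    for scanner_id in sorted(by_scanner):
        current: Optional[ExamInstance] = None
        open_start: Optional[LogEvent] = None
        counter = 0
        for idx, ev in by_scanner[scanner_id]:
            if ev.event_kind == "registration":
                # A sequence_end sharing the registration timestamp was
                # already handled (events are processed in order and ties
                # keep file order); close out the previous exam.
                if current is not None and open_start is not None:
                    rejects.append(
                        Reject(idx + 1, "sequence_start without sequence_end")
                    )
                    open_start = None
                counter += 1
                exam_id = str(
                    ev.payload.get("exam_id")
                    or f"{scanner_id or 'scanner'}-{counter:05d}"
                )
                current = ExamInstance(
                    exam_id=exam_id,
                    registration_time=ev.timestamp,
                    scanner_id=scanner_id,
                    approximate_age_years=float(
                        ev.payload.get("approximate_age_years", 0.0)
                    ),
                )
                exams.append(current)
                continue
            if current is None:
                rejects.append(
                    Reject(idx + 1, f"{ev.event_kind} before any registration")
                )
                continue
            if ev.event_kind == "sequence_start":
                if open_start is not None:
                    rejects.append(
                        Reject(idx + 1, "sequence_start without sequence_end")
                    )
                open_start = ev
            elif ev.event_kind == "sequence_end":
                if open_start is None or (
                    open_start.payload.get("raw_name") != ev.payload.get("raw_name")
                ):
                    rejects.append(
                        Reject(idx + 1, "sequence_end without matching sequence_start")
                    )
                    continue
                try:
                    seq = _sequence_from_payload(open_start, ev.timestamp)
                except (KeyError, TypeError, ValueError) as exc:
                    rejects.append(Reject(idx + 1, f"invalid sequence: {exc}"))
                    open_start = None
                    continue
                current.sequences.append(seq)
                current.table_positions.append(
                    (seq.start_time, seq.table_position_mm)
                )
                open_start = None
            elif ev.event_kind == "table_move":
                current.table_positions.append(
                    (ev.timestamp, float(ev.payload["position_mm"]))
                )
            elif ev.event_kind == "contrast_injection":
                current.contrast_given = True
        if open_start is not None:
            rejects.append(Reject(0, "sequence_start without sequence_end at EOF"))

    for exam in exams:
        exam.sequences.sort(key=lambda s: s.start_time)
        exam.table_positions.sort(key=lambda tp: tp[0])
        exam.aborted = len(exam.sequences) == 0

    exams.sort(key=lambda e: (e.registration_time, e.scanner_id))
    return AssemblyResult(exams=exams, rejects=rejects)


# ---------------------------------------------------------------------------
# Billing merge


def read_billing(stream: IO[str] | Iterable[str]) -> list:
    """Read the billing CSV dialect.

    Header is either ``exam_id,code_id,count`` or ``timestamp,code_id,count``.
    """
    reader = csv.DictReader(stream)
    fields = reader.fieldnames or []
    if "code_id" not in fields or "count" not in fields:
        raise ValueError("billing file must have code_id and count columns")
    records = []
    for row in reader:
        if "exam_id" in fields and row.get("exam_id"):
            records.append(
                BillingRecord(
                    code_id=row["code_id"], count=int(row["count"]),
                    exam_id=row["exam_id"],
                )
            )
        else:
            records.append(
                BillingRecord(
                    code_id=row["code_id"], count=int(row["count"]),
                    timestamp=_parse_ts(row["timestamp"]),
                )
            )
    return records


def write_billing(records: Sequence[BillingRecord], stream: IO[str]) -> None:
    by_id = all(r.exam_id is not None for r in records)
    writer = csv.writer(stream)
    if by_id:
        writer.writerow(["exam_id", "code_id", "count"])
        for r in records:
            writer.writerow([r.exam_id, r.code_id, r.count])
    else:
        writer.writerow(["timestamp", "code_id", "count"])
        for r in records:
            writer.writerow([_fmt_ts(r.timestamp), r.code_id, r.count])


def merge_billing(
    exams: Sequence[ExamInstance],
    billing: Sequence[BillingRecord],
    tolerance: timedelta = timedelta(minutes=30),
) -> MergeResult:
    """Populate each exam's labelset from billing records.

    Records keyed by exam id match directly; timestamp-keyed records
    match the unique exam whose span (padded by ``tolerance``) contains
    the timestamp.  A timestamp matching two exams raises
    :class:`MergeAmbiguityError`; records matching no exam land in the
    unmatched report.  Exams with no billing match keep an empty
    labelset and are flagged.
    """
    from .labels import Labelset  # local import to avoid a cycle

    by_id = {e.exam_id: e for e in exams}
    acc: dict[str, dict[str, int]] = {e.exam_id: {} for e in exams}
    unmatched: list[BillingRecord] = []

    for rec in billing:
        target: Optional[ExamInstance] = None
        if rec.exam_id is not None:
            target = by_id.get(rec.exam_id)
        else:
            hits = [
                e for e in exams
                if e.registration_time - tolerance <= rec.timestamp <= e.end_time + tolerance
            ]
            if len(hits) > 1:
                names = ", ".join(e.exam_id for e in hits)
                raise MergeAmbiguityError(
                    f"billing record {rec.code_id} at {rec.timestamp} matches "
                    f"multiple exams: {names}"
                )
            target = hits[0] if hits else None
        if target is None:
            unmatched.append(rec)
            continue
        acc[target.exam_id][rec.code_id] = (
            acc[target.exam_id].get(rec.code_id, 0) + rec.count
        )

    for exam in exams:
        counts = acc[exam.exam_id]
        exam.labelset = Labelset(counts)
        exam.no_billing_match = len(counts) == 0

    return MergeResult(exams=list(exams), unmatched=unmatched)
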
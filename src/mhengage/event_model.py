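"""Anonymized mobile-telemetry event schema, validation and JSON-lines I/O.

An event log is a JSON-lines file: one object per line with keys

    install_id  opaque per-installation identifier (string, nonempty)
    ts          UTC timestamp, integer epoch milliseconds
    event       event name (see :data:`EVENT_NAMES`)
    area        content-area label, present only for screen-context events
    duration_s  nonnegative seconds the user spent on the record
    payload     optional flat key->scalar map (assessment item/response,
                completed level, platform, ...)

Records are anonymized upstream; nothing here attempts identity resolution.
"""
from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping

import pandas as pd

log = logging.getLogger("mhengage.event_model")

EVENT_NAMES: tuple[str, ...] = (
    "launch",
    "eula_accepted",
    "screen_view",
    "exercise_started",
    "level_completed",
    "assessment_item",
    "assessment_completed",
    "other",
)

#: Content-area vocabulary. ``home`` is the hub screen and never counts as a
#: key content area in navigation analyses; ``other`` is the catch-all.
CONTENT_AREAS: tuple[str, ...] = (
    "training_plan",
    "practice_now",
    "build_expertise",
    "track_progress",
    "badges",
    "other",
    "home",
)

#: Areas counted as "key content areas" (everything except the home hub).
KEY_CONTENT_AREAS: tuple[str, ...] = tuple(a for a in CONTENT_AREAS if a != "home")

# Events that happen on a screen: content_area required for screen_view,
# allowed for exercise_started, forbidden elsewhere.
_AREA_REQUIRED = frozenset({"screen_view"})
_AREA_ALLOWED = frozenset({"screen_view", "exercise_started"})

_SCALAR = (str, int, float, bool)


@dataclass
class EventRecord:
    """One validated telemetry record."""

    install_id: str
    timestamp: int  # UTC epoch milliseconds
    event_name: str
    duration_s: float
    content_area: str | None = None
    payload: dict[str, Any] | None = None

    def to_json_obj(self) -> dict[str, Any]:
        obj: dict[str, Any] = {
            "install_id": self.install_id,
            "ts": self.timestamp,
            "event": self.event_name,
            "duration_s": self.duration_s,
        }
        if self.content_area is not None:
            obj["area"] = self.content_area
        if self.payload is not None:
            obj["payload"] = self.payload
        return obj


def validate_record(raw: Mapping[str, Any]) -> tuple[EventRecord | None, list[str]]:
    """Validate one raw JSON object against the event schema.

    Returns ``(record, [])`` on success or ``(None, violations)`` where
    *violations* is the complete list of schema problems; content errors
    never raise. Unknown event names and content-area labels are mapped to
    ``"other"`` with a warning rather than rejected, so an evolving app
    vocabulary does not invalidate historical logs.
    """
    errors: list[str] = []

    install_id = raw.get("install_id")
    if not isinstance(install_id, str) or not install_id:
        errors.append("install_id missing or empty")

    ts = raw.get("ts", raw.get("timestamp"))
    if isinstance(ts, bool) or not isinstance(ts, int):
        errors.append("ts missing or not an integer (epoch milliseconds)")
    elif abs(ts) > 4 * 10**15:  # ~year 129000; guards nonsense magnitudes
        errors.append("ts outside representable range")

    event = raw.get("event", raw.get("event_name"))
    if not isinstance(event, str) or not event:
        errors.append("event missing")
        event = None
    elif event not in EVENT_NAMES:
        log.warning("unknown event name %r mapped to 'other'", event)
        event = "other"

    dur = raw.get("duration_s")
    if isinstance(dur, bool) or not isinstance(dur, (int, float)):
        errors.append("duration_s missing or not numeric")
    elif dur < 0:
        errors.append("duration_s negative")

    area = raw.get("area", raw.get("content_area"))
    if area is not None:
        if not isinstance(area, str):
            errors.append("area not a string")
            area = None
        elif area not in CONTENT_AREAS:
            log.warning("unknown content area %r mapped to 'other'", area)
            area = "other"
    if event is not None:
        if event in _AREA_REQUIRED and area is None:
            errors.append(f"area required for event {event!r}")
        if area is not None and event not in _AREA_ALLOWED:
            errors.append(f"area not allowed for event {event!r}")

    payload = raw.get("payload")
    if payload is not None:
        if not isinstance(payload, Mapping):
            errors.append("payload not a mapping")
            payload = None
        else:
            bad = [k for k, v in payload.items() if v is not None and not isinstance(v, _SCALAR)]
            if bad:
                errors.append(f"payload values must be scalars: {bad}")
    if event == "assessment_item":
        if not isinstance(payload, Mapping) or "item" not in payload or "response" not in payload:
            errors.append("assessment_item payload must contain 'item' and 'response'")

    if errors:
        return None, errors
    return (
        EventRecord(
            install_id=install_id,
            timestamp=ts,
            event_name=event,
            duration_s=float(dur),
            content_area=area,
            payload=dict(payload) if payload is not None else None,
        ),
        [],
    )


@dataclass
class EventStream:
    """An ordered, validated collection of event records.

    Records are kept sorted by ``(install_id, timestamp)``; ties within an
    installation preserve input order (stable sort). The observation window
    ``[window_start, window_end]`` (epoch ms) bounds every timestamp and is
    the censoring horizon for all retention computations downstream.
    """

    records: list[EventRecord] = field(default_factory=list)
    source: str = ""
    window_start: int | None = None
    window_end: int | None = None

    @classmethod
    def from_records(
        cls,
        records: Iterable[EventRecord],
        source: str = "",
        window_start: int | None = None,
        window_end: int | None = None,
    ) -> "EventStream":
        recs = sorted(records, key=lambda r: (r.install_id, r.timestamp))
        if recs:
            tmin = min(r.timestamp for r in recs)
            tmax = max(r.timestamp for r in recs)
            if window_start is None:
                window_start = tmin
            if window_end is None:
                window_end = tmax
        stream = cls(recs, source=source, window_start=window_start, window_end=window_end)
        stream.validate()
        return stream

    def validate(self) -> None:
        prev_key: tuple[str, int] | None = None
        for r in self.records:
            key = (r.install_id, r.timestamp)
            if prev_key is not None and key < prev_key:
                raise ValueError("records not sorted by (install_id, timestamp)")
            prev_key = key
            if self.window_start is not None and r.timestamp < self.window_start:
                raise ValueError(f"timestamp {r.timestamp} before window_start")
            if self.window_end is not None and r.timestamp > self.window_end:
                raise ValueError(f"timestamp {r.timestamp} after window_end")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self.records)

    def install_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.install_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Columnar view of the stream (payload kept as an object column)."""
        return pd.DataFrame(
            {
                "install_id": [r.install_id for r in self.records],
                "ts": pd.array([r.timestamp for r in self.records], dtype="int64"),
                "event": [r.event_name for r in self.records],
                "area": [r.content_area for r in self.records],
                "duration_s": [r.duration_s for r in self.records],
                "payload": [r.payload for r in self.records],
            }
        )


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_event_log(
    path: str | Path,
    strict: bool = False,
    window_start: int | None = None,
    window_end: int | None = None,
) -> EventStream:
    """Read a JSON-lines event log into a sorted, validated :class:`EventStream`.

    In strict mode the first malformed line aborts with its line number; in
    non-strict mode malformed lines are skipped, counted and reported via the
    log. Gzip-compressed logs (``*.gz``) are read transparently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[EventRecord] = []
    n_bad = 0
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                raw = json.loads(line)
                if not isinstance(raw, Mapping):
                    raise ValueError("line is not a JSON object")
                rec, errs = validate_record(raw)
            except (json.JSONDecodeError, ValueError) as exc:
                rec, errs = None, [str(exc)]
            if rec is None:
                if strict:
                    raise ValueError(f"{path}:{lineno}: malformed record: {errs}")
                n_bad += 1
                continue
            records.append(rec)
    if n_bad:
        log.warning("%s: skipped %d malformed line(s)", path, n_bad)
    stream = EventStream.from_records(
        records, source=str(path), window_start=window_start, window_end=window_end
    )
    stream.n_skipped = n_bad  # type: ignore[attr-defined]
    return stream


def write_event_log(stream: EventStream, path: str | Path) -> int:
    """Write a stream as JSON-lines; returns the number of records written.

    ``read_event_log(write_event_log(s))`` reproduces *s* record for record.
    """
    stream.validate()
    path = Path(path)
    n = 0
    with _open_text(path, "w") as fh:
        for rec in stream.records:
            fh.write(json.dumps(rec.to_json_obj(), separators=(",", ":")))
            fh.write("\n")
            n += 1
    return n
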
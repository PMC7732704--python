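"""Sessionization: duration capping, visit clustering, session typing.

A *visit* is a maximal cluster of consecutive records for one installation
whose start-to-start gaps are all strictly below the inactivity threshold
(default 30 minutes); a gap of exactly the threshold starts a new visit.
Record durations are capped at 30 minutes unless the user configured a
longer value. *Events* are the records with nonzero duration — the unit of
in-app interaction; zero-duration records still anchor visit boundaries but
do not count as events.

A visit is *first-time* when it contains the end-user-license-agreement
acceptance event, *return* otherwise; installations that never accepted the
license have no classifiable visits (session_type ``None``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .event_model import EventRecord, EventStream

log = logging.getLogger("mhengage.sessionizer")

GAP_S_DEFAULT = 1800.0  # 30-minute inactivity threshold between events
CAP_S_DEFAULT = 1800.0  # 30-minute per-record duration cap

#: payload key a settings record may carry to raise the duration cap
USER_CAP_PAYLOAD_KEY = "duration_cap_s"

FIRST_TIME = "first_time"
RETURN = "return"


def cap_duration(
    duration_s: float, cap_s: float = CAP_S_DEFAULT, user_override_s: float | None = None
) -> float:
    """Cap a record duration at ``cap_s`` seconds, unless the user configured
    a longer cap (``user_override_s``), in which case the longer cap applies."""
    if duration_s < 0:
        raise ValueError("duration_s must be nonnegative")
    if cap_s <= 0:
        raise ValueError("cap_s must be positive")
    effective = cap_s
    if user_override_s is not None:
        if user_override_s < 0:
            raise ValueError("user_override_s must be nonnegative")
        if user_override_s > cap_s:
            effective = user_override_s
    return min(duration_s, effective)


def is_countable_event(record: EventRecord) -> bool:
    """A record counts as an event iff its duration field is nonzero."""
    return record.duration_s > 0


@dataclass
class Visit:
    """A cluster of records less than the gap threshold apart."""

    install_id: str
    visit_index: int  # 1-based
    start: int  # epoch ms of first record
    end: int  # epoch ms of last record
    events: list[EventRecord]
    active_seconds: float  # sum of capped durations of countable events
    content_areas_visited: list[str]  # non-home areas, in order, with repeats
    session_type: str | None = None  # first_time | return | None (unclassified)

    @property
    def n_events(self) -> int:
        return sum(1 for r in self.events if is_countable_event(r))


@dataclass
class UserTimeline:
    """All visits of one installation, chronologically ordered."""

    install_id: str
    visits: list[Visit]
    accepted_license: bool
    user_cap_override_s: float | None = None

    @property
    def first_use(self) -> int:
        return self.visits[0].start

    @property
    def last_use(self) -> int:
        return self.visits[-1].end

    def iter_events(self) -> Iterator[EventRecord]:
        for v in self.visits:
            yield from v.events


def _visit_from_events(
    install_id: str,
    index: int,
    events: list[EventRecord],
    cap_s: float,
    user_override_s: float | None,
) -> Visit:
    active = sum(
        cap_duration(r.duration_s, cap_s, user_override_s)
        for r in events
        if r.duration_s > 0
    )
    areas = [
        r.content_area
        for r in events
        if r.event_name == "screen_view" and r.content_area not in (None, "home")
    ]
    return Visit(
        install_id=install_id,
        visit_index=index,
        start=events[0].timestamp,
        end=events[-1].timestamp,
        events=events,
        active_seconds=active,
        content_areas_visited=areas,  # type: ignore[arg-type]
    )


def cluster_visits(
    events: Sequence[EventRecord],
    gap_s: float = GAP_S_DEFAULT,
    cap_s: float = CAP_S_DEFAULT,
    user_override_s: float | None = None,
) -> list[Visit]:
    """Partition one installation's sorted records into visits.

    A new visit starts whenever the start-to-start gap to the previous record
    is >= ``gap_s`` (strictly-less-than keeps records together).
    """
    if not events:
        return []
    install = events[0].install_id
    gap_ms = gap_s * 1000.0
    visits: list[Visit] = []
    current: list[EventRecord] = [events[0]]
    for prev, rec in zip(events, events[1:]):
        if rec.install_id != install:
            raise ValueError("cluster_visits expects records of a single installation")
        if rec.timestamp < prev.timestamp:
            raise ValueError("records must be sorted by timestamp")
        if rec.timestamp - prev.timestamp >= gap_ms:
            visits.append(
                _visit_from_events(install, len(visits) + 1, current, cap_s, user_override_s)
            )
            current = [rec]
        else:
            current.append(rec)
    visits.append(_visit_from_events(install, len(visits) + 1, current, cap_s, user_override_s))
    return visits


def classify_session(visit: Visit) -> str:
    """Type a visit by whether the license agreement was accepted in it."""
    if any(r.event_name == "eula_accepted" for r in visit.events):
        return FIRST_TIME
    return RETURN


def _find_user_cap(events: Iterable[EventRecord]) -> float | None:
    for r in events:
        if r.payload and USER_CAP_PAYLOAD_KEY in r.payload:
            try:
                return float(r.payload[USER_CAP_PAYLOAD_KEY])
            except (TypeError, ValueError):
                continue
    return None


def build_timeline(
    stream: EventStream,
    install_id: str,
    gap_s: float = GAP_S_DEFAULT,
    cap_s: float = CAP_S_DEFAULT,
) -> UserTimeline:
    """Assemble the capped, clustered, classified timeline of one installation."""
    events = [r for r in stream.records if r.install_id == install_id]
    if not events:
        raise KeyError(f"install_id {install_id!r} not present in stream")
    return _timeline_from_events(install_id, events, gap_s, cap_s)


def _timeline_from_events(
    install_id: str,
    events: list[EventRecord],
    gap_s: float,
    cap_s: float,
) -> UserTimeline:
    override = _find_user_cap(events)
    visits = cluster_visits(events, gap_s=gap_s, cap_s=cap_s, user_override_s=override)
    n_eula = sum(1 for r in events if r.event_name == "eula_accepted")
    if n_eula > 1:
        raise ValueError(f"{install_id}: {n_eula} license-acceptance events (expected at most 1)")
    accepted = n_eula == 1
    for v in visits:
        v.session_type = classify_session(v) if accepted else None
    return UserTimeline(
        install_id=install_id,
        visits=visits,
        accepted_license=accepted,
        user_cap_override_s=override,
    )


def iter_timelines(
    stream: EventStream, gap_s: float = GAP_S_DEFAULT, cap_s: float = CAP_S_DEFAULT
) -> Iterator[UserTimeline]:
    """Yield one timeline per installation, in stream order."""
    current_id: str | None = None
    bucket: list[EventRecord] = []
    for rec in stream.records:
        if rec.install_id != current_id:
            if bucket:
                yield _timeline_from_events(current_id, bucket, gap_s, cap_s)  # type: ignore[arg-type]
            current_id, bucket = rec.install_id, [rec]
        else:
            bucket.append(rec)
    if bucket:
        yield _timeline_from_events(current_id, bucket, gap_s, cap_s)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Vectorized path. Identical semantics to cluster_visits/iter_timelines, used
# by the pipeline for population-scale streams; equivalence is asserted in
# the test suite on randomized small streams.
# ---------------------------------------------------------------------------

def sessionize_frame(
    events: pd.DataFrame,
    gap_s: float = GAP_S_DEFAULT,
    cap_s: float = CAP_S_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sessionize a columnar event stream (see ``EventStream.to_frame``).

    Returns ``(events, visits)``: the input frame with ``visit_index`` and
    ``capped_s`` columns added, and a one-row-per-visit frame with columns
    install_id, visit_index, start, end, n_records, n_events, active_seconds,
    has_eula, session_type.

    User cap overrides (settings payloads) are not resolved on this path; the
    per-record cap is ``cap_s``.
    """
    ev = events.copy()
    if len(ev) == 0:
        visits = pd.DataFrame(
            columns=[
                "install_id", "visit_index", "start", "end", "n_records",
                "n_events", "active_seconds", "has_eula", "session_type",
            ]
        )
        ev["visit_index"] = pd.Series(dtype="int64")
        ev["capped_s"] = pd.Series(dtype="float64")
        return ev, visits
    ev = ev.sort_values(["install_id", "ts"], kind="stable").reset_index(drop=True)
    gap_ms = gap_s * 1000.0
    new_install = ev["install_id"].ne(ev["install_id"].shift())
    gap = ev["ts"].diff()
    new_visit = new_install | (gap >= gap_ms)
    ev["visit_index"] = new_visit.groupby(ev["install_id"], sort=False).cumsum().astype("int64")
    ev["capped_s"] = ev["duration_s"].clip(upper=cap_s)
    countable = ev["duration_s"] > 0

    grp = ev.groupby(["install_id", "visit_index"], sort=False)
    visits = grp.agg(
        start=("ts", "first"),
        end=("ts", "last"),
        n_records=("ts", "size"),
    ).reset_index()
    active = (
        ev.loc[countable]
        .groupby(["install_id", "visit_index"], sort=False)["capped_s"]
        .sum()
        .rename("active_seconds")
    )
    n_ev = (
        ev.loc[countable]
        .groupby(["install_id", "visit_index"], sort=False)["ts"]
        .size()
        .rename("n_events")
    )
    eula = (
        ev.loc[ev["event"] == "eula_accepted"]
        .groupby(["install_id", "visit_index"], sort=False)["ts"]
        .size()
        .rename("n_eula")
    )
    visits = (
        visits.merge(active, on=["install_id", "visit_index"], how="left")
        .merge(n_ev, on=["install_id", "visit_index"], how="left")
        .merge(eula, on=["install_id", "visit_index"], how="left")
    )
    visits["active_seconds"] = visits["active_seconds"].fillna(0.0)
    visits["n_events"] = visits["n_events"].fillna(0).astype("int64")
    visits["has_eula"] = visits["n_eula"].fillna(0) > 0
    visits = visits.drop(columns=["n_eula"])

    accepted = visits.groupby("install_id", sort=False)["has_eula"].transform("any")
    visits["session_type"] = np.where(
        accepted, np.where(visits["has_eula"], FIRST_TIME, RETURN), None
    )
    return ev, visits
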
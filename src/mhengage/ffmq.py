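"""FFMQ-SF (short-form Five-Facet Mindfulness Questionnaire) scoring.

The in-app assessment administers 4 of the short form's 5 facets —
*observing* (4 items), *acting with awareness* (5), *nonjudging of inner
experience* (5) and *nonreactivity to inner experience* (5) — 19 items total
on a 1-5 Likert scale; the *describing* facet is omitted. Reverse-keyed items
score ``6 - r``; facet scores are item sums, the total is the facet sum and
therefore lies in [19, 95].

The shipped key follows the published short-form facet assignment with the
describing facet removed: all acting-with-awareness and nonjudging items are
reverse-keyed. Apps may key items differently, so the key is loadable from
YAML.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .sessionizer import UserTimeline

log = logging.getLogger("mhengage.ffmq")

MS_PER_WEEK = 7 * 86_400_000

SUBSCALES: tuple[str, ...] = (
    "observing",
    "acting_with_awareness",
    "nonjudging",
    "nonreactivity",
)
#: conventional short labels, as used in figure legends
SUBSCALE_LABELS: dict[str, str] = {
    "observing": "Obs",
    "acting_with_awareness": "AA",
    "nonjudging": "NJIE",
    "nonreactivity": "NRIE",
}
_SUBSCALE_SIZES = {
    "observing": 4,
    "acting_with_awareness": 5,
    "nonjudging": 5,
    "nonreactivity": 5,
}
N_ITEMS = 19
TOTAL_MIN, TOTAL_MAX = 19, 95


@dataclass(frozen=True)
class FFMQKey:
    """Item -> facet assignment plus the reverse-keyed item set."""

    items: dict[str, str]  # item id -> subscale
    reverse: frozenset[str]
    scale_min: int = 1
    scale_max: int = 5

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"key must have {N_ITEMS} items, got {len(self.items)}")
        sizes = {s: 0 for s in SUBSCALES}
        for item, sub in self.items.items():
            if sub not in sizes:
                raise ValueError(f"unknown subscale {sub!r} for item {item!r}")
            sizes[sub] += 1
        if sizes != _SUBSCALE_SIZES:
            raise ValueError(f"subscale sizes {sizes} != required {_SUBSCALE_SIZES}")
        if not self.reverse <= set(self.items):
            raise ValueError("reverse set contains unknown items")

    def apply_reverse(self, item: str, response: int) -> int:
        if item in self.reverse:
            return self.scale_min + self.scale_max - response
        return response

    @classmethod
    def default(cls) -> "FFMQKey":
        items: dict[str, str] = {}
        for i in range(1, 5):
            items[f"obs{i}"] = "observing"
        for i in range(1, 6):
            items[f"aa{i}"] = "acting_with_awareness"
            items[f"nj{i}"] = "nonjudging"
            items[f"nr{i}"] = "nonreactivity"
        reverse = frozenset(k for k in items if k.startswith(("aa", "nj")))
        return cls(items=items, reverse=reverse)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FFMQKey":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            items=dict(raw["items"]),
            reverse=frozenset(raw.get("reverse", [])),
            scale_min=int(raw.get("scale_min", 1)),
            scale_max=int(raw.get("scale_max", 5)),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "items": dict(self.items),
                    "reverse": sorted(self.reverse),
                    "scale_min": self.scale_min,
                    "scale_max": self.scale_max,
                },
                fh,
                sort_keys=False,
            )


@dataclass
class FFMQScore:
    """Scored assessment occasion: four facet scores and their total."""

    install_id: str | None
    timestamp: int | None  # epoch ms of the completing event
    subscales: dict[str, int]
    total: int
    weeks_since_install: float | None = None
    level_at_assessment: int = 1

    @property
    def labeled(self) -> dict[str, int]:
        return {SUBSCALE_LABELS[s]: v for s, v in self.subscales.items()}


def score_occasion(
    responses: Mapping[str, int],
    key: FFMQKey | None = None,
    install_id: str | None = None,
    timestamp: int | None = None,
    weeks_since_install: float | None = None,
    level_at_assessment: int = 1,
) -> FFMQScore:
    """Score one complete response set.

    Raises on unknown items, responses outside the scale, or missing items
    (occasions with missing items are rejected rather than prorated).
    """
    key = key or FFMQKey.default()
    unknown = set(responses) - set(key.items)
    if unknown:
        raise ValueError(f"unknown item id(s): {sorted(unknown)}")
    missing = set(key.items) - set(responses)
    if missing:
        raise ValueError(f"missing item(s): {sorted(missing)}")
    sums = {s: 0 for s in SUBSCALES}
    for item, resp in responses.items():
        resp = int(resp)
        if not key.scale_min <= resp <= key.scale_max:
            raise ValueError(f"response {resp} for {item!r} outside "
                             f"[{key.scale_min}, {key.scale_max}]")
        sums[key.items[item]] += key.apply_reverse(item, resp)
    return FFMQScore(
        install_id=install_id,
        timestamp=timestamp,
        subscales=sums,
        total=sum(sums.values()),
        weeks_since_install=weeks_since_install,
        level_at_assessment=level_at_assessment,
    )


@dataclass
class AssessmentOccasion:
    responses: dict[str, int]
    timestamp: int
    level_at_assessment: int
    weeks_since_install: float


def extract_assessments(
    timeline: UserTimeline,
) -> tuple[list[AssessmentOccasion], int]:
    """Collect completed assessment occasions from a timeline.

    Within each visit, assessment-item events accumulate until an
    assessment-completed event closes the occasion; item runs never span
    visits. Runs left open at the end of a visit are *abandoned* — counted,
    not scored. Duplicate item ids within a run keep the last response, with
    a warning. Returns ``(occasions, n_abandoned)``.
    """
    occasions: list[AssessmentOccasion] = []
    n_abandoned = 0
    first_use = timeline.first_use
    level = 1
    for visit in timeline.visits:
        pending: dict[str, int] = {}
        for rec in visit.events:
            if rec.event_name == "level_completed" and rec.payload and "level" in rec.payload:
                level = max(level, int(rec.payload["level"]))
            elif rec.event_name == "assessment_item" and rec.payload:
                item = str(rec.payload.get("item"))
                if item in pending:
                    log.warning(
                        "%s: duplicate item %r in assessment run; keeping last",
                        timeline.install_id, item,
                    )
                pending[item] = int(rec.payload.get("response"))
            elif rec.event_name == "assessment_completed":
                if pending:
                    occasions.append(
                        AssessmentOccasion(
                            responses=pending,
                            timestamp=rec.timestamp,
                            level_at_assessment=level,
                            weeks_since_install=(rec.timestamp - first_use) / MS_PER_WEEK,
                        )
                    )
                    pending = {}
        if pending:
            n_abandoned += 1
    return occasions, n_abandoned


def score_timeline(
    timeline: UserTimeline, key: FFMQKey | None = None
) -> tuple[list[FFMQScore], int]:
    """Extract and score every completed occasion of a timeline; occasions
    that fail scoring (e.g. incomplete item sets) are dropped with a warning.
    Returns ``(scores, n_abandoned)``."""
    key = key or FFMQKey.default()
    occasions, n_abandoned = extract_assessments(timeline)
    scores: list[FFMQScore] = []
    for occ in occasions:
        try:
            scores.append(
                score_occasion(
                    occ.responses,
                    key,
                    install_id=timeline.install_id,
                    timestamp=occ.timestamp,
                    weeks_since_install=occ.weeks_since_install,
                    level_at_assessment=occ.level_at_assessment,
                )
            )
        except ValueError as exc:
            log.warning("%s: occasion not scored: %s", timeline.install_id, exc)
    return scores, n_abandoned
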
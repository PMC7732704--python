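"""Per-user engagement profiles, user categories, descriptive tables, retention.

The four engagement categories partition users by visit count: *exploratory*
(1 visit), *limited* (2-3), *moderate* (4-7), *committed* (>=8). Return use is
the proportion of all installations with any activity beyond a given window
after first use; rolling retention counts the distinct active days / ISO weeks
/ calendar months between first and final use. Grand means over users are
two-stage (within-user means first) so every user contributes equally.
"""
from __future__ import annotations

import logging
import math
import operator
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sessionizer import UserTimeline, is_countable_event

log = logging.getLogger("mhengage.engagement_metrics")

MS_PER_DAY = 86_400_000

CATEGORIES: tuple[str, ...] = ("exploratory", "limited", "moderate", "committed")
#: inclusive visit-count bands per category
CATEGORY_BANDS: dict[str, tuple[int, float]] = {
    "exploratory": (1, 1),
    "limited": (2, 3),
    "moderate": (4, 7),
    "committed": (8, math.inf),
}

#: (label, days) pairs for return-use windows. Month-based windows use
#: day-count conventions (30/91/182/365); configurable at call sites.
DEFAULT_RETENTION_WINDOWS: tuple[tuple[str, int], ...] = (
    ("after_first_day", 1),
    ("after_1_week", 7),
    ("after_1_month", 30),
    ("after_3_months", 91),
    ("after_6_months", 182),
    ("after_12_months", 365),
)

PROFILE_METRICS: tuple[str, ...] = (
    "level_achieved",
    "retention_weeks",
    "active_minutes",
    "n_visits",
    "mean_visit_minutes",
    "n_events",
)


def proportion_pct(numerator: int, denominator: int) -> float:
    """Percentage ``100*n/d`` rounded half-up to 2 decimals (as printed in
    descriptive reports)."""
    numerator = operator.index(numerator)
    denominator = operator.index(denominator)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def categorize(n_visits: int) -> str:
    """Band a visit count into the four-category engagement taxonomy."""
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    for cat, (lo, hi) in CATEGORY_BANDS.items():
        if lo <= n_visits <= hi:
            return cat
    raise AssertionError("unreachable: bands partition the positive integers")


def two_stage_mean(values: Mapping[str, Sequence[float]] | Iterable[Sequence[float]]) -> float:
    """Mean over users of within-user means (each user weighs equally)."""
    groups = list(values.values()) if isinstance(values, Mapping) else list(values)
    groups = [g for g in groups if len(g) > 0]
    if not groups:
        raise ValueError("two_stage_mean requires at least one non-empty group")
    return float(np.mean([np.mean(g) for g in groups]))


@dataclass
class EngagementProfile:
    install_id: str
    platform: str  # android | ios | unknown
    license_accepted: bool
    n_visits: int
    n_events: int
    active_minutes: float
    retention_weeks: int
    level_achieved: int
    mean_visit_minutes: float
    category: str
    first_use: int = 0  # epoch ms
    last_use: int = 0


def profile_user(timeline: UserTimeline) -> EngagementProfile:
    """Aggregate one timeline into a per-installation engagement profile.

    ``active_minutes`` sums capped countable durations; ``retention_weeks``
    is whole weeks elapsed between first and final use; ``level_achieved``
    is the highest completed training-plan level (1 when none was completed);
    platform is read from launch-event payloads.
    """
    n_visits = len(timeline.visits)
    if n_visits < 1:
        raise ValueError("timeline has no visits")
    n_events = sum(v.n_events for v in timeline.visits)
    active_s = sum(v.active_seconds for v in timeline.visits)
    first, last = timeline.first_use, timeline.last_use
    retention_weeks = int((last - first) // MS_PER_DAY) // 7
    level = 1
    platform = "unknown"
    for rec in timeline.iter_events():
        if rec.event_name == "level_completed" and rec.payload and "level" in rec.payload:
            level = max(level, int(rec.payload["level"]))
        elif rec.event_name == "launch" and rec.payload and platform == "unknown":
            platform = str(rec.payload.get("platform", "unknown"))
    return EngagementProfile(
        install_id=timeline.install_id,
        platform=platform,
        license_accepted=timeline.accepted_license,
        n_visits=n_visits,
        n_events=n_events,
        active_minutes=active_s / 60.0,
        retention_weeks=retention_weeks,
        level_achieved=level,
        mean_visit_minutes=active_s / 60.0 / n_visits,
        category=categorize(n_visits),
        first_use=first,
        last_use=last,
    )


def profiles_to_frame(profiles: Iterable[EngagementProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])


def profiles_from_frames(events: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Vectorized profiles from ``sessionize_frame`` output (one row per
    installation); column-for-column equivalent to :func:`profile_user`."""
    prof = visits.groupby("install_id", sort=False).agg(
        n_visits=("visit_index", "max"),
        n_events=("n_events", "sum"),
        active_seconds=("active_seconds", "sum"),
        first_use=("start", "min"),
        last_use=("end", "max"),
        license_accepted=("has_eula", "any"),
    )
    prof["active_minutes"] = prof["active_seconds"] / 60.0
    prof["mean_visit_minutes"] = prof["active_minutes"] / prof["n_visits"]
    prof["retention_weeks"] = (
        ((prof["last_use"] - prof["first_use"]) // MS_PER_DAY) // 7
    ).astype("int64")

    levels = events.loc[events["event"] == "level_completed", ["install_id", "payload"]].copy()
    if len(levels):
        levels["level"] = levels["payload"].map(
            lambda p: int(p["level"]) if p and "level" in p else 1
        )
        lvl = levels.groupby("install_id")["level"].max()
        prof["level_achieved"] = lvl.reindex(prof.index).fillna(1).astype("int64")
    else:
        prof["level_achieved"] = 1

    launches = events.loc[events["event"] == "launch", ["install_id", "payload"]]
    if len(launches):
        plat = (
            launches.assign(
                platform=launches["payload"].map(
                    lambda p: p.get("platform", "unknown") if p else "unknown"
                )
            )
            .groupby("install_id")["platform"]
            .first()
        )
        prof["platform"] = plat.reindex(prof.index).fillna("unknown")
    else:
        prof["platform"] = "unknown"

    prof["category"] = pd.cut(
        prof["n_visits"],
        bins=[0, 1, 3, 7, np.inf],
        labels=CATEGORIES,
    ).astype(str)
    prof = prof.drop(columns=["active_seconds"]).reset_index()
    cols = [
        "install_id", "platform", "license_accepted", "n_visits", "n_events",
        "active_minutes", "retention_weeks", "level_achieved",
        "mean_visit_minutes", "category", "first_use", "last_use",
    ]
    return prof[cols]


# ---------------------------------------------------------------------------
# Descriptive tables
# ---------------------------------------------------------------------------

def _sd(x: pd.Series) -> float:
    return float(x.std(ddof=1)) if len(x) > 1 else 0.0


def descriptive_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-group descriptive statistics of the use variables.

    One row for the full sample plus one per engagement category, with
    download counts, license-acceptance and platform splits (count and
    percentage), and mean/SD/min/max for each use metric.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles")
    rows = []
    groups: list[tuple[str, pd.DataFrame]] = [("all", profiles)]
    for cat in CATEGORIES:
        sub = profiles[profiles["category"] == cat]
        if len(sub) == 0:
            log.warning("descriptive_table: empty group %r dropped", cat)
            continue
        groups.append((cat, sub))
    for name, sub in groups:
        n = len(sub)
        lic = int(sub["license_accepted"].sum())
        android = int((sub["platform"] == "android").sum())
        ios = int((sub["platform"] == "ios").sum())
        row: dict[str, object] = {
            "group": name,
            "downloads": n,
            "license_accepted_n": lic,
            "license_accepted_pct": proportion_pct(lic, n),
            "android_n": android,
            "android_pct": proportion_pct(android, n),
            "ios_n": ios,
            "ios_pct": proportion_pct(ios, n),
        }
        for m in PROFILE_METRICS:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_sd"] = _sd(sub[m])
            row[f"{m}_min"] = float(sub[m].min())
            row[f"{m}_max"] = float(sub[m].max())
        rows.append(row)
    return pd.DataFrame(rows)


def nearest_rank_percentile(values: Sequence[float], p: float) -> float:
    """Nearest-rank (type-1) percentile: the ``ceil(p/100 * n)``-th smallest."""
    if not 0 < p <= 100:
        raise ValueError("p must be in (0, 100]")
    xs = np.sort(np.asarray(values, dtype=float))
    if xs.size == 0:
        raise ValueError("empty values")
    k = max(1, math.ceil(p / 100.0 * xs.size))
    return float(xs[k - 1])


def percentile_table(
    profiles: pd.DataFrame, percentiles: Sequence[float] = (25, 50, 75, 90)
) -> pd.DataFrame:
    """Nearest-rank percentiles of each use metric, per group (full sample and
    each engagement category)."""
    if len(profiles) == 0:
        raise ValueError("no profiles")
    rows = []
    groups: list[tuple[str, pd.DataFrame]] = [("all", profiles)]
    groups += [
        (cat, profiles[profiles["category"] == cat])
        for cat in CATEGORIES
        if (profiles["category"] == cat).any()
    ]
    for metric in PROFILE_METRICS:
        for name, sub in groups:
            row: dict[str, object] = {"metric": metric, "group": name, "downloads": len(sub)}
            for p in percentiles:
                row[f"p{int(p)}"] = nearest_rank_percentile(sub[metric].to_numpy(), p)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

@dataclass
class RetentionReport:
    """Return-use proportions over increasing windows after first use."""

    labels: list[str]
    window_days: list[int]
    numerators: list[int]
    denominator: int
    pct: list[float] = field(default_factory=list)
    stated_pct: list[float] | None = None  # externally printed values, if linting
    censored_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pct:
            self.pct = [proportion_pct(n, self.denominator) for n in self.numerators]


def return_use(
    profiles: pd.DataFrame,
    windows: Sequence[tuple[str, int]] = DEFAULT_RETENTION_WINDOWS,
    window_end: int | None = None,
) -> RetentionReport:
    """Proportion of installations with any activity beyond each window after
    first use. Denominator is all installations; windows longer than the
    observation span are flagged as censored (their proportions understate
    eventual return)."""
    days = [d for _, d in windows]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("windows must be sorted ascending")
    first = profiles["first_use"].to_numpy()
    last = profiles["last_use"].to_numpy()
    denom = len(profiles)
    if denom == 0:
        raise ValueError("no profiles")
    numerators = [int((last > first + d * MS_PER_DAY).sum()) for _, d in windows]
    censored = []
    if window_end is not None:
        span_days = (window_end - int(first.min())) / MS_PER_DAY
        censored = [lbl for lbl, d in windows if d > span_days]
        if censored:
            log.warning("return_use: windows %s exceed the observation span", censored)
    return RetentionReport(
        labels=[lbl for lbl, _ in windows],
        window_days=list(days),
        numerators=numerators,
        denominator=denom,
        censored_labels=censored,
    )


def lint_retention_report(report: RetentionReport) -> list[str]:
    """Consistency checks on a retention report; returns human-readable issues.

    Flags (a) non-monotone return-use proportions (they must not increase as
    the window lengthens) and (b) any stated percentage that does not
    recompute from its own numerator/denominator — the check that catches
    transcription errors in printed reports.
    """
    issues: list[str] = []
    seq = report.stated_pct if report.stated_pct is not None else report.pct
    for i in range(1, len(seq)):
        if seq[i] > seq[i - 1]:
            issues.append(
                f"{report.labels[i]}: proportion {seq[i]} exceeds "
                f"{report.labels[i - 1]} proportion {seq[i - 1]} (must be non-increasing)"
            )
    if report.stated_pct is not None:
        for lbl, n, stated in zip(report.labels, report.numerators, report.stated_pct):
            recomputed = proportion_pct(n, report.denominator)
            if abs(recomputed - stated) > 0.005:
                issues.append(
                    f"{lbl}: stated {stated}% but {n}/{report.denominator} = {recomputed}%"
                )
    return issues


def rolling_retention(timeline: UserTimeline) -> tuple[int, int, int]:
    """Distinct active (UTC) days, ISO weeks and calendar months containing at
    least one countable event."""
    ts = [r.timestamp for r in timeline.iter_events() if is_countable_event(r)]
    if not ts:
        return (0, 0, 0)
    t = pd.to_datetime(pd.Series(ts), unit="ms", utc=True)
    iso = t.dt.isocalendar()
    days = t.dt.date.nunique()
    weeks = len(set(zip(iso["year"], iso["week"])))
    months = len(set(zip(t.dt.year, t.dt.month)))
    return (int(days), int(weeks), int(months))


def rolling_retention_frame(events: pd.DataFrame) -> pd.DataFrame:
    """Per-installation rolling retention (distinct active days/weeks/months),
    vectorized over a columnar event stream."""
    ev = events.loc[events["duration_s"] > 0, ["install_id", "ts"]].copy()
    if len(ev) == 0:
        return pd.DataFrame(columns=["install_id", "active_days", "active_weeks", "active_months"])
    t = pd.to_datetime(ev["ts"], unit="ms", utc=True)
    iso = t.dt.isocalendar()
    ev["day"] = t.dt.strftime("%Y-%m-%d")
    ev["week"] = iso["year"].astype(str) + "-W" + iso["week"].astype(str)
    ev["month"] = t.dt.strftime("%Y-%m")
    out = ev.groupby("install_id", sort=False).agg(
        active_days=("day", "nunique"),
        active_weeks=("week", "nunique"),
        active_months=("month", "nunique"),
    )
    return out.reset_index()
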
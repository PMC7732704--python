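"""Synthetic telemetry generator with analytically known ground truth.

Emulates the statistical structure the analysis pipeline assumes: a
four-category user mixture with heavy right skew in visits and events, a
license-acceptance event opening the first visit, inter-visit gaps that are
always at or above the 30-minute sessionization threshold (so the
sessionizer's visit counts equal the generator's intended counts by
construction), within-visit gaps always below it, content-area navigation
frequencies by session type, level progression over a 14-level training plan
with assessment prompts at levels 1, 7 and 14, and FFMQ-SF item responses
whose occasion totals follow a latent mixed model

    total = beta0 + beta1 * g(engagement) + u_user + eps,
    u ~ N(0, tau^2), eps ~ N(0, sigma^2)

(or, in ``time_cubic`` mode, a cubic rise-plateau-rise trajectory in weeks
since install). Ground truth retains every latent quantity so each pipeline
stage can be validated against it. All randomness flows from one
``numpy.random.default_rng`` seed; identical seeds give byte-identical logs.

Distribution defaults are stylized: category mix 0.39/0.32/0.18/0.11,
Android share 0.629, license acceptance 0.878, committed visit counts from a
shifted negative binomial capped at 506, log-normal inter-visit gaps and
event durations. Real gap and duration distributions for this kind of app
are unpublished; every distribution is a config field.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .event_model import EventRecord, EventStream, KEY_CONTENT_AREAS
from .ffmq import FFMQKey, SUBSCALES

log = logging.getLogger("mhengage.synthetic_data")

MS_PER_S = 1000
S_PER_DAY = 86_400
S_PER_WEEK = 7 * S_PER_DAY

# default observation window: 2018-08-01 .. 2019-04-08 UTC (epoch ms)
DEFAULT_WINDOW_START = 1_533_081_600_000
DEFAULT_WINDOW_END = 1_554_681_600_000

CATEGORIES = ("exploratory", "limited", "moderate", "committed")

# Rise-plateau-rise cubic for time_cubic mode: derivative k*(w-16)^2 + c with
# k=0.0045, c=0.02 — strictly positive, near zero on weeks ~8-24.
TIME_CUBIC_COEFFS = (52.0, 1.172, -0.072, 0.0015)


@dataclass
class OutcomeConfig:
    """Latent outcome model for FFMQ-SF occasion totals."""

    mode: str = "engagement"  # engagement | time_cubic
    beta0: float = 55.0
    beta1: float = 3.0
    transform: str = "log1p"  # g() applied to cumulative active minutes
    time_coeffs: tuple[float, float, float, float] = TIME_CUBIC_COEFFS
    tau: float = 6.0  # SD of the per-user random intercept
    sigma: float = 5.0  # SD of the occasion residual

    def latent_total(self, cum_active_minutes: float, weeks: float, u: float,
                     eps: float) -> float:
        if self.mode == "engagement":
            g = np.log1p(cum_active_minutes) if self.transform == "log1p" else cum_active_minutes
            return self.beta0 + self.beta1 * g + u + eps
        a0, a1, a2, a3 = self.time_coeffs
        return a0 + a1 * weeks + a2 * weeks**2 + a3 * weeks**3 + u + eps


def _normalized(d: dict[str, float]) -> dict[str, float]:
    s = sum(d.values())
    return {k: v / s for k, v in d.items()}


# First-area mixtures (including "none" = home-only session) by session type.
FIRST_AREA_FIRST_TIME = _normalized({
    "none": 0.2974,
    "training_plan": 0.4443,
    "practice_now": 0.1618,
    "build_expertise": 0.0303,
    "track_progress": 0.0165,
    "badges": 0.0056,
    "other": 0.0441,
})
FIRST_AREA_RETURN = _normalized({
    "none": 0.3836,
    "training_plan": 0.2623,
    "practice_now": 0.2816,
    "track_progress": 0.0314,
    "build_expertise": 0.0281,
    "badges": 0.0042,
    "other": 0.0088,
})


@dataclass
class PopulationConfig:
    """All knobs of the synthetic population; defaults are the study
    conditions the pipeline is designed for."""

    n_users: int = 1000
    category_mix: dict[str, float] = field(default_factory=lambda: {
        "exploratory": 0.39, "limited": 0.32, "moderate": 0.18, "committed": 0.11,
    })
    android_p: float = 0.629
    license_accept_p: float = 0.878
    # visit-count distributions within each category band
    limited_p2: float = 0.6  # P(2 visits | limited); else 3
    moderate_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)  # visits 4..7
    committed_nb_r: float = 0.26  # shifted NB: 8 + NB(r, mean)
    committed_nb_mean: float = 11.3
    committed_cap: int = 506
    # inter-visit gaps (log-normal, days), floored above the session threshold
    intervisit_median_days: float = 2.0
    intervisit_sigma: float = 1.1
    min_intervisit_s: float = 1830.0
    # within-visit structure
    events_per_visit_mu: float = 2.2  # log-scale; median ~9 records/visit
    events_per_visit_sigma: float = 0.8
    zero_duration_p: float = 0.15
    duration_median_s: float = 15.0
    duration_sigma: float = 1.2
    intra_gap_mean_s: float = 40.0
    intra_gap_max_s: float = 1500.0
    # navigation
    first_area_first_time: dict[str, float] = field(
        default_factory=lambda: dict(FIRST_AREA_FIRST_TIME))
    first_area_return: dict[str, float] = field(
        default_factory=lambda: dict(FIRST_AREA_RETURN))
    extra_area_p: float = 0.30  # geometric continuation to further distinct areas
    # training plan & assessments
    level_up_p: float = 0.10  # per-visit chance of completing the next level
    assessment_compliance: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 7: 0.5, 14: 0.5})
    abandon_p: float = 0.08  # chance a declined prompt leaves a partial item run
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    window_start: int = DEFAULT_WINDOW_START
    window_end: int = DEFAULT_WINDOW_END

    def validate(self) -> list[str]:
        errs: list[str] = []
        if self.n_users < 0:
            errs.append("n_users must be >= 0")
        for name, mix in [
            ("category_mix", self.category_mix),
            ("first_area_first_time", self.first_area_first_time),
            ("first_area_return", self.first_area_return),
        ]:
            if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-6:
                errs.append(f"{name} must be nonnegative and sum to 1")
        if set(self.category_mix) != set(CATEGORIES):
            errs.append("category_mix must cover exactly the four categories")
        for name, p in [
            ("android_p", self.android_p), ("license_accept_p", self.license_accept_p),
            ("limited_p2", self.limited_p2), ("zero_duration_p", self.zero_duration_p),
            ("extra_area_p", self.extra_area_p), ("level_up_p", self.level_up_p),
            ("abandon_p", self.abandon_p),
        ]:
            if not 0 <= p <= 1:
                errs.append(f"{name} must be in [0, 1]")
        for name, v in [
            ("intervisit_median_days", self.intervisit_median_days),
            ("intervisit_sigma", self.intervisit_sigma),
            ("duration_median_s", self.duration_median_s),
            ("duration_sigma", self.duration_sigma),
            ("intra_gap_mean_s", self.intra_gap_mean_s),
            ("committed_nb_r", self.committed_nb_r),
            ("committed_nb_mean", self.committed_nb_mean),
        ]:
            if v <= 0:
                errs.append(f"{name} must be > 0")
        if self.min_intervisit_s < 1800:
            errs.append("min_intervisit_s must be >= the 1800 s session threshold")
        if self.intra_gap_max_s >= 1800:
            errs.append("intra_gap_max_s must stay below the 1800 s session threshold")
        if abs(sum(self.moderate_probs) - 1.0) > 1e-6 or len(self.moderate_probs) != 4:
            errs.append("moderate_probs must be 4 probabilities summing to 1")
        if self.outcome.mode not in ("engagement", "time_cubic"):
            errs.append("outcome.mode must be 'engagement' or 'time_cubic'")
        if self.window_start >= self.window_end:
            errs.append("window_start must precede window_end")
        return errs


@dataclass
class OccasionTruth:
    timestamp: int  # epoch ms
    cum_active_minutes: float
    weeks_since_install: float
    latent_total: float
    realized_total: int


@dataclass
class UserTruth:
    install_id: str
    category: str
    platform: str
    accepted: bool
    n_visits: int
    active_seconds: float
    n_countable_events: int
    level_achieved: int
    u: float
    occasions: list[OccasionTruth] = field(default_factory=list)


@dataclass
class GroundTruth:
    config: PopulationConfig
    users: list[UserTruth] = field(default_factory=list)

    def users_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.users:
            d = {k: v for k, v in vars(t).items() if k != "occasions"}
            d["n_occasions"] = len(t.occasions)
            rows.append(d)
        return pd.DataFrame(rows)

    def occasions_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.users:
            for o in t.occasions:
                rows.append({"install_id": t.install_id, **vars(o)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _draw_visit_count(category: str, cfg: PopulationConfig, rng: np.random.Generator) -> int:
    if category == "exploratory":
        return 1
    if category == "limited":
        return 2 if rng.random() < cfg.limited_p2 else 3
    if category == "moderate":
        return int(rng.choice([4, 5, 6, 7], p=cfg.moderate_probs))
    r = cfg.committed_nb_r
    p = r / (r + cfg.committed_nb_mean)
    return min(8 + int(rng.negative_binomial(r, p)), cfg.committed_cap)


def _draw_duration(cfg: PopulationConfig, rng: np.random.Generator) -> float:
    if rng.random() < cfg.zero_duration_p:
        return 0.0
    return round(float(rng.lognormal(math.log(cfg.duration_median_s), cfg.duration_sigma)), 1)


def _decompose_total(
    total: int, rng: np.random.Generator, key: FFMQKey
) -> tuple[dict[str, int], dict[str, int]]:
    """Spread an occasion total across the 19 items (each in [1,5]) exactly.

    Returns ``(scored_item_values, subscale_sums)`` on the *scored* scale
    (before un-reversing for storage)."""
    total = int(np.clip(total, 19, 95))
    items = list(key.items)
    q, r = divmod(total, 19)
    vals = {it: q for it in items}
    if r:
        for idx in rng.choice(len(items), size=r, replace=False):
            vals[items[idx]] += 1
    subs = {s: 0 for s in SUBSCALES}
    for it, v in vals.items():
        subs[key.items[it]] += v
    return vals, subs


# ---------------------------------------------------------------------------
# user-level generation
# ---------------------------------------------------------------------------

_PROMPT_LEVELS = (1, 7, 14)


def generate_user(
    category: str,
    config: PopulationConfig,
    rng: np.random.Generator,
    install_id: str,
    key: FFMQKey | None = None,
) -> tuple[list[EventRecord], UserTruth]:
    """Generate one installation's full event sequence plus its ground truth.

    Visit-boundary guarantees: consecutive records within a visit are less
    than 30 minutes apart, the first record of each later visit is at least
    ``min_intervisit_s`` after the previous record, so sessionization with the
    default gap recovers exactly the intended visits.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    key = key or FFMQKey.default()
    platform = "android" if rng.random() < config.android_p else "ios"
    accepted = bool(rng.random() < config.license_accept_p)
    u = float(rng.normal(0.0, config.outcome.tau))
    n_visits = _draw_visit_count(category, config, rng)

    # events are built per visit with offsets relative to the visit start;
    # inter-visit gaps are assembled afterwards (and squeezed, floored at
    # min_intervisit_s, when a long tenure would overflow the window)
    per_visit: list[list[tuple[float, str, str | None, float, dict | None]]] = []
    occasions: list[tuple[int, float, float, float, int]] = []
    # (visit_idx, rel_offset, cum_min, latent, realized)
    cum_active_s = 0.0
    n_countable = 0
    level = 1
    pending_prompts: set[int] = {1}
    t = 0.0  # seconds since visit start

    def emit(event: str, area: str | None, duration: float, payload: dict | None = None) -> None:
        nonlocal t, cum_active_s, n_countable
        per_visit[-1].append((t, event, area, duration, payload))
        if duration > 0:
            cum_active_s += min(duration, 1800.0)
            n_countable += 1
        t += min(float(rng.exponential(config.intra_gap_mean_s)) + 0.5, config.intra_gap_max_s)

    for v in range(1, n_visits + 1):
        per_visit.append([])
        t = 0.0
        emit("launch", None, _draw_duration(config, rng), {"platform": platform})
        if v == 1 and accepted:
            emit("eula_accepted", None, 2.0)
        emit("screen_view", "home", _draw_duration(config, rng))
        session_type = "first_time" if (v == 1 and accepted) else "return"
        mix = (config.first_area_first_time if session_type == "first_time"
               else config.first_area_return)
        labels = list(mix)
        first = str(rng.choice(labels, p=[mix[l] for l in labels]))
        visited: list[str] = []
        if first != "none":
            visited.append(first)
            emit("screen_view", first, _draw_duration(config, rng))
            remaining = [a for a in KEY_CONTENT_AREAS if a not in visited]
            while remaining and rng.random() < config.extra_area_p:
                nxt = str(rng.choice(remaining))
                visited.append(nxt)
                emit("screen_view", nxt, _draw_duration(config, rng))
                remaining.remove(nxt)
        n_extra = max(0, int(round(rng.lognormal(
            config.events_per_visit_mu, config.events_per_visit_sigma))) - len(visited) - 2)
        for _ in range(n_extra):
            if visited and rng.random() < 0.6:
                emit("screen_view", str(rng.choice(visited)), _draw_duration(config, rng))
            elif visited and rng.random() < 0.5:
                emit("exercise_started", str(rng.choice(visited)), _draw_duration(config, rng))
            else:
                emit("other", None, _draw_duration(config, rng))
        if level < 14 and rng.random() < config.level_up_p:
            level += 1
            emit("level_completed", None, 1.0, {"level": level})
            if level in _PROMPT_LEVELS:
                pending_prompts.add(level)
        for lvl in sorted(pending_prompts):
            pending_prompts.discard(lvl)
            compliance = config.assessment_compliance.get(lvl, 0.0)
            if rng.random() < compliance:
                cum_min = cum_active_s / 60.0
                # time_cubic mode uses the pre-squeeze week estimate here;
                # realized week offsets are recorded in the ground truth
                weeks = (sum(pv[-1][0] for pv in per_visit[:-1])
                         + t + (v - 1) * config.intervisit_median_days * S_PER_DAY) / S_PER_WEEK
                eps = float(rng.normal(0.0, config.outcome.sigma))
                latent = config.outcome.latent_total(cum_min, weeks, u, eps)
                realized = int(np.clip(round(latent), 19, 95))
                vals, _ = _decompose_total(realized, rng, key)
                for it in key.items:
                    stored = key.scale_min + key.scale_max - vals[it] if it in key.reverse else vals[it]
                    emit("assessment_item", None, 0.5, {"item": it, "response": stored})
                emit("assessment_completed", None, 1.0)
                occasions.append((v - 1, per_visit[-1][-1][0], cum_min, latent, realized))
            elif rng.random() < config.abandon_p:
                n_part = int(rng.integers(1, 19))
                for it in list(key.items)[:n_part]:
                    emit("assessment_item", None, 0.5,
                         {"item": it, "response": int(rng.integers(1, 6))})

    # assemble visit start offsets; squeeze gaps into the window if needed
    durations = [pv[-1][0] for pv in per_visit]
    gaps = [
        max(float(rng.lognormal(
            math.log(config.intervisit_median_days * S_PER_DAY), config.intervisit_sigma)),
            config.min_intervisit_s)
        for _ in range(n_visits - 1)
    ]
    window_span_s = (config.window_end - config.window_start) / MS_PER_S
    margin_s = S_PER_DAY
    available = window_span_s - margin_s - sum(durations)
    if gaps and sum(gaps) > available:
        f = max(available, len(gaps) * config.min_intervisit_s) / sum(gaps)
        gaps = [max(g * f, config.min_intervisit_s) for g in gaps]
    starts = [0.0]
    for d, g in zip(durations, gaps):
        starts.append(starts[-1] + d + g)

    span_ms = int((starts[-1] + durations[-1]) * MS_PER_S) + 1
    window_span = config.window_end - config.window_start
    install_ts = config.window_start + int(rng.integers(0, max(1, window_span - span_ms)))

    records = [
        EventRecord(
            install_id=install_id,
            timestamp=install_ts + int((starts[vi] + off) * MS_PER_S),
            event_name=ev,
            duration_s=dur,
            content_area=area,
            payload=payload,
        )
        for vi, pv in enumerate(per_visit)
        for off, ev, area, dur, payload in pv
    ]
    truth = UserTruth(
        install_id=install_id,
        category=category,
        platform=platform,
        accepted=accepted,
        n_visits=n_visits,
        active_seconds=cum_active_s,
        n_countable_events=n_countable,
        level_achieved=level,
        u=u,
        occasions=[
            OccasionTruth(
                timestamp=install_ts + int((starts[vi] + off) * MS_PER_S),
                cum_active_minutes=cum_min,
                weeks_since_install=(starts[vi] + off) / S_PER_WEEK,
                latent_total=latent,
                realized_total=realized,
            )
            for vi, off, cum_min, latent, realized in occasions
        ],
    )
    return records, truth


def _install_id(rng: np.random.Generator, index: int) -> str:
    hexdigits = "0123456789abcdef"
    tag = "".join(hexdigits[d] for d in rng.integers(0, 16, size=12))
    return f"{tag}-{index:06d}"


def generate_population(
    config: PopulationConfig, seed: int | np.random.Generator = 0
) -> tuple[EventStream, GroundTruth]:
    """Generate the full synthetic population as a validated event stream plus
    ground truth. Deterministic given the seed."""
    errs = config.validate()
    if errs:
        raise ValueError("invalid PopulationConfig: " + "; ".join(errs))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    key = FFMQKey.default()
    cats = list(config.category_mix)
    probs = [config.category_mix[c] for c in cats]
    truth = GroundTruth(config=config)
    all_records: list[EventRecord] = []
    for i in range(config.n_users):
        category = str(rng.choice(cats, p=probs))
        records, ut = generate_user(category, config, rng, _install_id(rng, i), key)
        all_records.extend(records)
        truth.users.append(ut)
    stream = EventStream.from_records(
        all_records,
        source=f"synthetic(n={config.n_users})",
        window_start=config.window_start,
        window_end=config.window_end,
    )
    return stream, truth


# ---------------------------------------------------------------------------
# occasion-level fast path (no event materialization) for estimator studies
# ---------------------------------------------------------------------------

# stylized per-category (median active minutes, mean span weeks)
_CATEGORY_ENGAGEMENT = {
    "exploratory": (1.0, 0.0),
    "limited": (4.0, 3.8),
    "moderate": (11.0, 7.8),
    "committed": (40.0, 12.8),
}


def generate_outcome_table(
    config: PopulationConfig,
    seed: int | np.random.Generator = 0,
    n_users: int | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Draw occasion-level analysis rows directly from the latent outcome
    model, without materializing event streams.

    This is the replication-scale harness for estimator studies (bias, CI
    coverage, curve shapes): per-user engagement totals and assessment
    occasions are sampled from the same latent model the event-level
    generator uses, and the returned frame has the exact schema of
    ``assemble_long_table``. Returns ``(table, truth)`` where truth records
    the generating parameters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_users if n_users is None else n_users
    oc = config.outcome
    key = FFMQKey.default()
    cats = list(config.category_mix)
    probs = [config.category_mix[c] for c in cats]
    rows: list[dict[str, Any]] = []
    for i in range(n):
        category = str(rng.choice(cats, p=probs))
        n_visits = _draw_visit_count(category, config, rng)
        med_min, mean_weeks = _CATEGORY_ENGAGEMENT[category]
        total_min = float(rng.lognormal(math.log(med_min), 1.0))
        span_weeks = float(rng.exponential(mean_weeks)) if mean_weeks > 0 else 0.0
        n_events = max(1, int(round(n_visits * rng.lognormal(2.45, 0.5))))
        level = 1 + int(rng.binomial(n_visits, config.level_up_p))
        level = min(level, 14)
        u = float(rng.normal(0.0, oc.tau))
        if oc.mode == "time_cubic":
            n_occ = 2
            weeks_at = np.sort(rng.uniform(0.0, 32.0, size=n_occ))
            fracs = weeks_at / 32.0
        else:
            prompts = [lvl for lvl in _PROMPT_LEVELS if level >= lvl]
            keep = [rng.random() < config.assessment_compliance.get(lvl, 0.0)
                    for lvl in prompts]
            n_occ = sum(keep)
            if n_occ == 0:
                continue
            fracs = np.sort(rng.uniform(0.05, 1.0, size=n_occ))
            weeks_at = span_weeks * fracs
        for j in range(n_occ):
            cum_min = total_min * float(fracs[j])
            eps = float(rng.normal(0.0, oc.sigma))
            latent = oc.latent_total(cum_min, float(weeks_at[j]), u, eps)
            realized = int(np.clip(round(latent), 19, 95))
            _, subs = _decompose_total(realized, rng, key)
            rows.append({
                "install_id": f"sim-{i:06d}",
                "occasion_ts": None,
                "weeks_since_install": float(weeks_at[j]),
                "level_at_assessment": level,
                "total": realized,
                "Obs": subs["observing"],
                "AA": subs["acting_with_awareness"],
                "NJIE": subs["nonjudging"],
                "NRIE": subs["nonreactivity"],
                "active_minutes": cum_min if oc.mode == "engagement" else total_min,
                "n_visits": n_visits,
                "n_events": n_events,
                "level_achieved": level,
            })
    table = pd.DataFrame(rows)
    truth = {
        "mode": oc.mode,
        "beta0": oc.beta0,
        "beta1": oc.beta1,
        "transform": oc.transform,
        "time_coeffs": list(oc.time_coeffs),
        "tau": oc.tau,
        "sigma": oc.sigma,
    }
    return table, truth
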
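"""One-command orchestration: ingest -> sessionize -> profile -> retention ->
navigation -> FFMQ scoring -> models -> report.

Runs are fully deterministic for a given config (and seed, when the input is
synthetic): every artifact is a CSV or Markdown file with no wall-clock
content, so reruns are byte-identical. Every percentage printed in the
report is recomputed from the adjacent counts, and a self-consistency linter
verifies that before the report is written.
"""
from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import engagement_metrics as em
from . import navigation as nav
from . import outcome_model as om
from .event_model import EventStream, read_event_log
from .ffmq import FFMQKey, score_timeline
from .sessionizer import iter_timelines, sessionize_frame
from .synthetic_data import PopulationConfig, generate_population

log = logging.getLogger("mhengage.pipeline")

ARTIFACTS = (
    "visits.csv", "profiles.csv", "table1.csv", "table2.csv", "retention.csv",
    "table3.csv", "ffmq_scores.csv", "models.csv", "report.md",
)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "out"
    input_path: str | None = None  # JSON-lines event log; mutually exclusive with synthetic
    synthetic_n_users: int | None = None
    seed: int = 0
    gap_minutes: float = 30.0
    cap_minutes: float = 30.0
    retention_windows: list[tuple[str, int]] = field(
        default_factory=lambda: list(em.DEFAULT_RETENTION_WINDOWS))
    ffmq_key_path: str | None = None
    model_degree: int = 3
    window_start: int | None = None
    window_end: int | None = None
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        windows = raw.pop("retention_windows", None)
        cfg = cls(**raw)
        if windows is not None:
            cfg.retention_windows = [(str(l), int(d)) for l, d in windows]
        return cfg

    def validate(self) -> list[str]:
        errs: list[str] = []
        if (self.input_path is None) == (self.synthetic_n_users is None):
            errs.append("exactly one of input_path / synthetic_n_users is required")
        if self.input_path is not None and not Path(self.input_path).exists():
            errs.append(f"input_path {self.input_path!r} does not exist")
        if self.ffmq_key_path is not None and not Path(self.ffmq_key_path).exists():
            errs.append(f"ffmq_key_path {self.ffmq_key_path!r} does not exist")
        if self.gap_minutes <= 0 or self.cap_minutes <= 0:
            errs.append("gap_minutes and cap_minutes must be positive")
        if self.model_degree not in (1, 2, 3):
            errs.append("model_degree must be 1, 2 or 3")
        days = [d for _, d in self.retention_windows]
        if days != sorted(days):
            errs.append("retention_windows must be sorted ascending")
        if (self.window_start is not None and self.window_end is not None
                and self.window_start >= self.window_end):
            errs.append("window_start must precede window_end")
        return errs


_PCT_RX = re.compile(r"(\d+(?:\.\d+)?)% \((\d+)/(\d+)\)")


def lint_report_percentages(markdown: str) -> list[str]:
    """Check every ``pct% (n/d)`` phrase in a report recomputes exactly."""
    issues = []
    for m in _PCT_RX.finditer(markdown):
        stated, n, d = float(m.group(1)), int(m.group(2)), int(m.group(3))
        recomputed = em.proportion_pct(n, d)
        if abs(recomputed - stated) > 0.005:
            issues.append(f"{m.group(0)}: recomputes to {recomputed}%")
    return issues


def _pctphrase(n: int, d: int) -> str:
    return f"{em.proportion_pct(n, d):.2f}% ({n}/{d})"


def _load_stream(config: RunConfig) -> EventStream:
    if config.input_path is not None:
        return read_event_log(
            config.input_path,
            window_start=config.window_start,
            window_end=config.window_end,
        )
    pop = PopulationConfig(n_users=config.synthetic_n_users)
    if config.window_start is not None:
        pop.window_start = config.window_start
    if config.window_end is not None:
        pop.window_end = config.window_end
    stream, _ = generate_population(pop, seed=config.seed)
    return stream


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns a summary dict with artifact paths,
    per-stage status, and headline numbers. Raises on config errors; stage
    failures are recorded and dependent stages skipped."""
    errs = config.validate()
    if errs:
        raise ValueError("invalid RunConfig: " + "; ".join(errs))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.verbosity, logging.INFO))
    gap_s = config.gap_minutes * 60.0
    cap_s = config.cap_minutes * 60.0
    key = FFMQKey.from_yaml(config.ffmq_key_path) if config.ffmq_key_path else FFMQKey.default()
    status: dict[str, str] = {}
    summary: dict[str, Any] = {"outdir": str(outdir), "stages": status}

    stream = _load_stream(config)
    if len(stream) == 0:
        raise ValueError("input stream contains no valid records")
    status["ingest"] = f"ok ({len(stream)} records)"

    events = stream.to_frame()
    events, visits = sessionize_frame(events, gap_s=gap_s, cap_s=cap_s)
    visits_out = visits.copy()
    visits_out["active_minutes"] = visits_out["active_seconds"] / 60.0
    visits_out.to_csv(outdir / "visits.csv", index=False)
    status["sessionize"] = f"ok ({len(visits)} visits)"

    profiles = em.profiles_from_frames(events, visits)
    rolling = em.rolling_retention_frame(events)
    profiles = profiles.merge(rolling, on="install_id", how="left")
    for c in ("active_days", "active_weeks", "active_months"):
        profiles[c] = profiles[c].fillna(0).astype("int64")
    profiles.to_csv(outdir / "profiles.csv", index=False)
    status["profile"] = f"ok ({len(profiles)} users)"

    table1 = em.descriptive_table(profiles)
    table1.to_csv(outdir / "table1.csv", index=False)
    table2 = em.percentile_table(profiles)
    table2.to_csv(outdir / "table2.csv", index=False)
    report = em.return_use(profiles, config.retention_windows, window_end=stream.window_end)
    ret_issues = em.lint_retention_report(report)
    for issue in ret_issues:
        log.warning("retention lint: %s", issue)
    retention_df = pd.DataFrame({
        "window": report.labels,
        "days": report.window_days,
        "numerator": report.numerators,
        "denominator": report.denominator,
        "pct": report.pct,
        "censored": [l in report.censored_labels for l in report.labels],
    })
    retention_df.to_csv(outdir / "retention.csv", index=False)
    status["retention"] = "ok"

    nav_rows = nav.nav_rows_from_frames(events, visits)
    tables = nav.navigation_summary(nav_rows)
    table3 = (pd.concat([t.to_frame() for t in tables], ignore_index=True)
              if tables else pd.DataFrame())
    tests = nav.navigation_tests(tables)
    table3.to_csv(outdir / "table3.csv", index=False)
    tests.to_csv(outdir / "table3_tests.csv", index=False)
    status["navigation"] = f"ok ({len(tables)} panels)"

    scores = []
    n_abandoned = 0
    for tl in iter_timelines(stream, gap_s=gap_s, cap_s=cap_s):
        s, ab = score_timeline(tl, key)
        scores.extend(s)
        n_abandoned += ab
    scores_df = pd.DataFrame(
        [{
            "install_id": s.install_id, "occasion_ts": s.timestamp,
            "weeks_since_install": s.weeks_since_install,
            "level_at_assessment": s.level_at_assessment,
            **s.labeled, "total": s.total,
        } for s in scores]
    )
    scores_df.to_csv(outdir / "ffmq_scores.csv", index=False)
    status["ffmq"] = f"ok ({len(scores)} occasions, {n_abandoned} abandoned)"

    models = pd.DataFrame()
    if len(scores) >= 10:
        try:
            long_table = om.assemble_long_table(scores, profiles)
            models = om.fit_battery(long_table, degree=config.model_degree)
            status["models"] = "ok"
        except (ValueError, RuntimeError) as exc:
            status["models"] = f"failed: {exc}"
            log.error("model stage failed: %s", exc)
    else:
        status["models"] = "skipped: fewer than 10 scored occasions"
    models.to_csv(outdir / "models.csv", index=False)

    md = _render_report(profiles, report, ret_issues, tables, tests, scores_df, models)
    issues = lint_report_percentages(md)
    if issues:
        raise AssertionError(f"report self-consistency lint failed: {issues}")
    (outdir / "report.md").write_text(md, encoding="utf-8")
    status["report"] = "ok"
    summary["artifacts"] = [str(outdir / a) for a in ARTIFACTS]
    summary["n_users"] = len(profiles)
    summary["n_visits"] = int(len(visits))
    summary["n_occasions"] = int(len(scores_df))
    return summary


def _render_report(
    profiles: pd.DataFrame,
    retention: em.RetentionReport,
    ret_issues: list[str],
    tables: list[nav.NavigationTable],
    tests: pd.DataFrame,
    scores_df: pd.DataFrame,
    models: pd.DataFrame,
) -> str:
    n = len(profiles)
    android = int((profiles["platform"] == "android").sum())
    lic = int(profiles["license_accepted"].sum())
    lines = [
        "# Engagement analysis report", "",
        "## Reach", "",
        f"- Unique installations analyzed: {n}",
        f"- Android share: {_pctphrase(android, n)}; iOS share: {_pctphrase(n - android, n)}",
        f"- License accepted: {_pctphrase(lic, n)}", "",
        "## Use", "",
    ]
    for cat in em.CATEGORIES:
        c = int((profiles["category"] == cat).sum())
        lo, hi = em.CATEGORY_BANDS[cat]
        band = f"{lo}" if lo == hi else (f">={lo}" if hi == float("inf") else f"{lo}-{int(hi)}")
        lines.append(f"- {cat} users ({band} visits): {_pctphrase(c, n)}")
    lines += [
        "",
        f"- Mean visits per user: {profiles['n_visits'].mean():.1f} "
        f"(SD {profiles['n_visits'].std(ddof=1):.1f})",
        f"- Mean events per user: {profiles['n_events'].mean():.1f} "
        f"(SD {profiles['n_events'].std(ddof=1):.1f})",
        f"- Mean active minutes per user: {profiles['active_minutes'].mean():.1f} "
        f"(SD {profiles['active_minutes'].std(ddof=1):.1f})",
        "", "## Retention", "",
    ]
    for lbl, num in zip(retention.labels, retention.numerators):
        suffix = " [censored]" if lbl in retention.censored_labels else ""
        lines.append(f"- Returned {lbl.replace('_', ' ')}: "
                     f"{_pctphrase(num, retention.denominator)}{suffix}")
    if ret_issues:
        lines += ["", "Retention lint issues:"] + [f"- {i}" for i in ret_issues]
    lines += ["", "## Navigation", ""]
    for t in tables:
        if t.panel != "first_area":
            continue
        top = max(zip(t.counts, t.labels))
        lines.append(
            f"- {t.session_type} sessions, most common first content area: "
            f"{top[1]} at {_pctphrase(top[0], t.denominator)}")
    for _, row in tests.iterrows():
        p = "<.001" if row["p_value"] < 0.001 else f"{row['p_value']:.3f}"
        lines.append(f"- {row['panel']}: chi-square {row['chi2']:.1f} "
                     f"(df {int(row['df'])}), P {p}")
    lines += ["", "## Mindfulness outcomes", ""]
    lines.append(f"- Scored assessment occasions: {len(scores_df)}")
    if len(scores_df):
        lines.append(f"- Mean total score: {scores_df['total'].mean():.1f}")
    if len(models):
        ok = models[models["error"] == ""]
        for (outcome, pred), sub in ok.groupby(["outcome", "predictor"], sort=False):
            r2 = sub["r_squared"].iloc[0]
            lines.append(f"- {outcome} ~ poly({pred}): R^2 = {r2:.2f}")
    lines.append("")
    return "\n".join(lines)
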
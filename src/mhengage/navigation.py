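"""Click-stream navigation analysis by session type.

Three panels, mirroring a detailed session analysis of first-time versus
returning sessions:

* **first_area** — the first key content area entered in each session
  (sessions that never leave the home screen are excluded from this panel's
  denominator);
* **any_area** — every distinct key content area a session entered (a session
  contributes one count per distinct area, so denominators exceed session
  counts);
* **n_distinct_areas** — the distribution of the number of distinct key
  content areas per session, over all sessions.

The home screen is a hub, never a content area. Between-group differences are
tested with a Pearson chi-square on the 2 x k contingency table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engagement_metrics import proportion_pct
from .event_model import KEY_CONTENT_AREAS
from .sessionizer import FIRST_TIME, RETURN, Visit

log = logging.getLogger("mhengage.navigation")

PANELS = ("first_area", "any_area", "n_distinct_areas")


def first_content_area(visit: Visit) -> str | None:
    """Label of the first key content area entered in a visit, or ``None`` for
    home-only (or empty) visits."""
    for area in visit.content_areas_visited:
        return area
    return None


def visit_nav_row(visit: Visit) -> dict[str, object]:
    """Per-visit navigation facts used by the panel summaries."""
    distinct = list(dict.fromkeys(visit.content_areas_visited))
    return {
        "install_id": visit.install_id,
        "visit_index": visit.visit_index,
        "session_type": visit.session_type,
        "first_area": first_content_area(visit),
        "distinct_areas": distinct,
        "n_distinct": len(distinct),
    }


@dataclass
class NavigationTable:
    """One panel x session-type block of the session analysis."""

    panel: str
    session_type: str
    labels: list[str]
    counts: list[int]
    denominator: int

    @property
    def pct(self) -> list[float]:
        return [proportion_pct(c, self.denominator) for c in self.counts]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "panel": self.panel,
                "session_type": self.session_type,
                "label": self.labels,
                "count": self.counts,
                "denominator": self.denominator,
                "pct": self.pct,
            }
        )


def nav_rows_from_visits(visits: Iterable[Visit]) -> pd.DataFrame:
    return pd.DataFrame([visit_nav_row(v) for v in visits])


def nav_rows_from_frames(events: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-visit navigation facts from ``sessionize_frame`` output."""
    screens = events.loc[
        (events["event"] == "screen_view")
        & events["area"].notna()
        & (events["area"] != "home"),
        ["install_id", "visit_index", "area"],
    ]
    first = (
        screens.groupby(["install_id", "visit_index"], sort=False)["area"]
        .first()
        .rename("first_area")
    )
    ndistinct = (
        screens.groupby(["install_id", "visit_index"], sort=False)["area"]
        .nunique()
        .rename("n_distinct")
    )
    distinct = (
        screens.drop_duplicates()
        .groupby(["install_id", "visit_index"], sort=False)["area"]
        .agg(list)
        .rename("distinct_areas")
    )
    out = (
        visits[["install_id", "visit_index", "session_type"]]
        .merge(first, on=["install_id", "visit_index"], how="left")
        .merge(ndistinct, on=["install_id", "visit_index"], how="left")
        .merge(distinct, on=["install_id", "visit_index"], how="left")
    )
    out["n_distinct"] = out["n_distinct"].fillna(0).astype("int64")
    out["distinct_areas"] = out["distinct_areas"].map(
        lambda x: x if isinstance(x, list) else []
    )
    out["first_area"] = out["first_area"].where(out["first_area"].notna(), None)
    return out


def navigation_summary(nav_rows: pd.DataFrame) -> list[NavigationTable]:
    """Build the three panels for each classifiable session type.

    Sessions with ``session_type`` ``None`` (installations that never accepted
    the license) are excluded, with a logged count.
    """
    n_uncl = int(nav_rows["session_type"].isna().sum())
    if n_uncl:
        log.info("navigation_summary: %d unclassified session(s) excluded", n_uncl)
    rows = nav_rows[nav_rows["session_type"].notna()]
    tables: list[NavigationTable] = []
    area_labels = sorted(KEY_CONTENT_AREAS)
    max_distinct = int(rows["n_distinct"].max()) if len(rows) else 0
    distinct_labels = [str(k) for k in range(max(max_distinct, 1) + 1)]
    for stype in (FIRST_TIME, RETURN):
        sub = rows[rows["session_type"] == stype]
        if len(sub) == 0:
            continue
        with_first = sub[sub["first_area"].notna()]
        counts = with_first["first_area"].value_counts()
        tables.append(
            NavigationTable(
                panel="first_area",
                session_type=stype,
                labels=area_labels,
                counts=[int(counts.get(a, 0)) for a in area_labels],
                denominator=int(len(with_first)),
            )
        )
        exploded = sub["distinct_areas"].explode().dropna()
        acounts = exploded.value_counts()
        tables.append(
            NavigationTable(
                panel="any_area",
                session_type=stype,
                labels=area_labels,
                counts=[int(acounts.get(a, 0)) for a in area_labels],
                denominator=int(len(exploded)),
            )
        )
        dcounts = sub["n_distinct"].value_counts()
        tables.append(
            NavigationTable(
                panel="n_distinct_areas",
                session_type=stype,
                labels=distinct_labels,
                counts=[int(dcounts.get(int(k), 0)) for k in distinct_labels],
                denominator=int(len(sub)),
            )
        )
    return tables


def compare_session_types(
    counts_first: Sequence[int],
    counts_return: Sequence[int],
    drop_empty: bool = True,
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on the 2 x k table of
    first-time vs returning counts over identical labels.

    Labels with zero total are dropped when ``drop_empty`` (they carry no
    information and would make expected counts zero); otherwise they raise.
    Returns ``(statistic, df, p_value)``.
    """
    a = np.asarray(counts_first, dtype=float)
    b = np.asarray(counts_return, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share labels")
    total = a + b
    if (total == 0).any():
        if not drop_empty:
            raise ValueError("zero-expected cell (set drop_empty=True to collapse)")
        keep = total > 0
        a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least two non-empty labels")
    table = np.vstack([a, b])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table")
    if np.array_equal(a / a.sum() if a.sum() else a, b / b.sum() if b.sum() else b):
        # identical distributions: chi-square is exactly 0
        return 0.0, int(a.size - 1), 1.0
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def navigation_tests(tables: list[NavigationTable]) -> pd.DataFrame:
    """Between-group chi-square per panel; returns a tidy frame."""
    rows = []
    for panel in PANELS:
        ft = [t for t in tables if t.panel == panel and t.session_type == FIRST_TIME]
        rt = [t for t in tables if t.panel == panel and t.session_type == RETURN]
        if not ft or not rt:
            continue
        f, r = ft[0], rt[0]
        labels = sorted(set(f.labels) | set(r.labels), key=lambda x: (len(x), x))
        cf = [f.counts[f.labels.index(l)] if l in f.labels else 0 for l in labels]
        cr = [r.counts[r.labels.index(l)] if l in r.labels else 0 for l in labels]
        try:
            stat, df, p = compare_session_types(cf, cr)
        except ValueError as exc:
            log.warning("navigation_tests: %s panel skipped: %s", panel, exc)
            continue
        rows.append({"panel": panel, "chi2": stat, "df": df, "p_value": p})
    return pd.DataFrame(rows)
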
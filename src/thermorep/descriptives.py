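"""Descriptive layer: annual article/participant tables, decade averages,
sample-size medians, and the orientation/phase reporting breakdown.

Studies are partitioned into three categories — women-only (no men),
men-only (no women), mixed (both) — and counted per calendar year, with
percentages relative to the annual totals. Aggregates matching the
published decade tables ship as packaged fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._formatting import percent
from .data_model import DEFAULT_WINDOW, YES, StudyRecord, YearWindow

ARTICLE_COLUMNS = ("articles_total", "articles_women_only", "articles_men_only", "articles_both")
PARTICIPANT_COLUMNS = (
    "participants_total",
    "participants_women_only",
    "participants_men_only",
    "participants_both_women",
    "participants_both_men",
)


@dataclass(frozen=True)
class AnnualSummary:
    """One year's article and participant counts by study category."""

    year: int
    articles_total: int = 0
    articles_women_only: int = 0
    articles_men_only: int = 0
    articles_both: int = 0
    participants_total: int = 0
    participants_women_only: int = 0
    participants_men_only: int = 0
    participants_both_women: int = 0
    participants_both_men: int = 0

    def __post_init__(self) -> None:
        if (
            self.articles_women_only + self.articles_men_only + self.articles_both
            != self.articles_total
        ):
            raise ValueError(f"{self.year}: article categories do not sum to the total")
        parts = (
            self.participants_women_only
            + self.participants_men_only
            + self.participants_both_women
            + self.participants_both_men
        )
        if parts != self.participants_total:
            raise ValueError(f"{self.year}: participant categories do not sum to the total")

    def article_percentages(self) -> dict[str, float]:
        """Category percentages of the annual article total, one decimal, half-up."""
        return {
            col: percent(getattr(self, col), self.articles_total)
            for col in ARTICLE_COLUMNS[1:]
        }

    def participant_percentages(self) -> dict[str, float]:
        return {
            col: percent(getattr(self, col), self.participants_total)
            for col in PARTICIPANT_COLUMNS[1:]
        }


def annual_summary(
    records: Sequence[StudyRecord], window: YearWindow = DEFAULT_WINDOW
) -> list[AnnualSummary]:
    """Per-year counts of articles and participants by category.

    Every year in the window yields a row; years without records are
    all-zero. Categories partition the record set: women-only iff
    ``n_men == 0``, men-only iff ``n_women == 0``, mixed otherwise.
    """
    out = []
    for year in window.years:
        year_recs = [r for r in records if r.year == year]
        wo = [r for r in year_recs if r.n_men == 0]
        mo = [r for r in year_recs if r.n_women == 0]
        both = [r for r in year_recs if r.n_women > 0 and r.n_men > 0]
        out.append(
            AnnualSummary(
                year=year,
                articles_total=len(year_recs),
                articles_women_only=len(wo),
                articles_men_only=len(mo),
                articles_both=len(both),
                participants_total=sum(r.total for r in year_recs),
                participants_women_only=sum(r.n_women for r in wo),
                participants_men_only=sum(r.n_men for r in mo),
                participants_both_women=sum(r.n_women for r in both),
                participants_both_men=sum(r.n_men for r in both),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[AnnualSummary]) -> pd.DataFrame:
    """Annual summaries as a DataFrame indexed by year."""
    rows = [{f.name: getattr(s, f.name) for f in fields(AnnualSummary)} for s in summaries]
    return pd.DataFrame(rows).set_index("year")


def load_packaged_tables() -> list[AnnualSummary]:
    """The packaged decade aggregates (annual article and participant counts)."""
    data = resources.files("thermorep") / "data"
    t1 = pd.read_csv(str(data / "table1_articles.csv"))
    t2 = pd.read_csv(str(data / "table2_participants.csv"))
    merged = t1.merge(t2, on="year")
    return [AnnualSummary(**row) for row in merged.to_dict(orient="records")]


def decade_averages(
    summaries: Sequence[AnnualSummary], *, ddof: int = 1
) -> pd.DataFrame:
    """Mean and SD per count column across the window, with percentage columns.

    The SD denominator defaults to n−1 (``ddof=1``), the spreadsheet
    convention the published table is consistent with; ``ddof=0`` gives
    the population form. Values are unrounded; use
    :func:`thermorep._formatting.round_half_up` at display time.
    """
    if not summaries:
        raise ValueError("decade_averages requires at least one annual summary")
    frame = summaries_to_frame(summaries)
    pct = pd.DataFrame(
        [{**s.article_percentages(), **s.participant_percentages()} for s in summaries],
        index=frame.index,
    ).add_suffix("_pct")
    full = pd.concat([frame, pct], axis=1)
    return pd.DataFrame({"mean": full.mean(), "sd": full.std(ddof=ddof)})


def sample_size_medians(
    records: Sequence[StudyRecord],
) -> dict[str, dict[str, float]]:
    """Median and quartiles of per-study sample sizes by category.

    Mixed studies contribute their women and men counts to two separate
    distributions (``mixed_women``, ``mixed_men``). Empty categories are
    absent from the result rather than reported as zero. Quartiles use
    linear interpolation (the common type-7 convention).
    """
    pools: dict[str, list[int]] = {
        "women_only": [r.n_women for r in records if r.n_men == 0],
        "men_only": [r.n_men for r in records if r.n_women == 0],
        "mixed_women": [r.n_women for r in records if r.n_women > 0 and r.n_men > 0],
        "mixed_men": [r.n_men for r in records if r.n_women > 0 and r.n_men > 0],
    }
    out = {}
    for name, sizes in pools.items():
        if not sizes:
            continue
        q1, med, q3 = np.percentile(sizes, [25, 50, 75])
        out[name] = {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(sizes)}
    return out


def women_inclusion_breakdown(records: Sequence[StudyRecord]) -> dict:
    """Orientation/phase reporting percentages among articles that include women.

    Returns, as display-rounded percentages: the share of women-including
    articles not reporting menstrual orientation; among reporters, the
    share of articles involving each orientation category (an article with
    groups in several categories counts toward each); the share of
    women-including articles controlling menstrual phase; and among
    phase-controllers, the share per phase label.
    """
    with_women = [r for r in records if r.includes_women]
    if not with_women:
        raise ValueError("no records include women")
    n = len(with_women)
    reporters = [r for r in with_women if r.orientation_reported == YES]
    not_reporting = n - len(reporters)
    orientation = {}
    if reporters:
        for cat in sorted({c for r in reporters for c in r.orientation_counts}):
            involving = sum(1 for r in reporters if r.orientation_counts.get(cat, 0) > 0)
            orientation[cat] = percent(involving, len(reporters))
    phase_controllers = [r for r in with_women if r.phase_reported == YES]
    phase = {}
    if phase_controllers:
        for label in sorted({r.phase_label for r in phase_controllers if r.phase_label}):
            phase[label] = percent(
                sum(1 for r in phase_controllers if r.phase_label == label),
                len(phase_controllers),
            )
    return {
        "n_articles_with_women": n,
        "pct_not_reporting_orientation": percent(not_reporting, n),
        "orientation_category_pct": orientation,
        "pct_phase_controlled": percent(len(phase_controllers), n),
        "phase_label_pct": phase,
    }
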
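"""Study-level records and their CSV interchange format.

One record per reviewed article: publication year, female and male
participant counts, and (for articles that include women) whether the
menstrual orientation of participants was reported, the per-orientation
head counts, and whether menstrual-cycle phase was controlled.

The modelling observation derived from a record is the pair
``(t, y)`` where ``t`` is the year index (2010 -> 0) and
``y = n_women / (n_women + n_men)`` is the female proportion, exactly 0
for men-only and exactly 1 for women-only studies — the response of the
zero-one-inflated beta regression.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Ternary flag values used for orientation/phase reporting.
YES, NO, NA = "yes", "no", "NA"
TERNARY = (YES, NO, NA)

ORIENTATION_CATEGORIES = (
    "natural-menstruating",
    "oral-contraceptive",
    "IUD-or-implant",
    "pregnant",
    "postmenopausal",
    "secondary-amenorrheic",
    "oligomenorrheic",
    "unspecified",
)

PHASE_LABELS = ("follicular", "early-follicular", "luteal", "placebo-pill", "other", "none")

CSV_HEADER = (
    "study_id",
    "year",
    "n_women",
    "n_men",
    "orientation_reported",
    "orientation_counts",
    "phase_reported",
    "phase_label",
)


@dataclass(frozen=True)
class YearWindow:
    """Inclusive calendar-year window of the review (default 2010–2019)."""

    start: int = 2010
    end: int = 2019

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end precedes start")

    def __contains__(self, year: int) -> bool:
        return self.start <= year <= self.end

    @property
    def years(self) -> range:
        return range(self.start, self.end + 1)

    @property
    def n_years(self) -> int:
        return self.end - self.start + 1


DEFAULT_WINDOW = YearWindow()


class RecordError(ValueError):
    """Raised for records or CSV rows violating the data contract."""


@dataclass(frozen=True)
class StudyRecord:
    """One reviewed article's extracted participant and reporting fields.

    Transgender participants are counted within the gender group the
    source article reports them in; there is no separate field.
    Missing orientation detail is the explicit category ``unspecified``.
    """

    study_id: str
    year: int
    n_women: int
    n_men: int
    orientation_reported: str = NA
    orientation_counts: Mapping[str, int] = field(default_factory=dict)
    phase_reported: str = NA
    phase_label: str | None = None

    def __post_init__(self) -> None:
        if self.n_women < 0 or self.n_men < 0:
            raise RecordError(f"{self.study_id}: negative participant count")
        if self.n_women + self.n_men < 1:
            raise RecordError(f"{self.study_id}: study has no participants")
        if self.orientation_reported not in TERNARY:
            raise RecordError(f"{self.study_id}: orientation_reported must be one of {TERNARY}")
        if self.phase_reported not in TERNARY:
            raise RecordError(f"{self.study_id}: phase_reported must be one of {TERNARY}")
        if self.n_women == 0 and (self.orientation_reported != NA or self.phase_reported != NA):
            raise RecordError(
                f"{self.study_id}: men-only study must carry not-applicable reporting flags"
            )
        for cat, count in self.orientation_counts.items():
            if cat not in ORIENTATION_CATEGORIES:
                raise RecordError(f"{self.study_id}: unknown orientation category {cat!r}")
            if count < 0:
                raise RecordError(f"{self.study_id}: negative orientation count for {cat}")
        if sum(self.orientation_counts.values()) > self.n_women:
            raise RecordError(f"{self.study_id}: orientation counts exceed n_women")
        if self.phase_label is not None and self.phase_label not in PHASE_LABELS:
            raise RecordError(f"{self.study_id}: unknown phase label {self.phase_label!r}")

    @property
    def total(self) -> int:
        return self.n_women + self.n_men

    @property
    def includes_women(self) -> bool:
        return self.n_women >= 1


@dataclass(frozen=True)
class ProportionObservation:
    """Year index and female proportion ``y = n/N`` of one study.

    ``y`` is exactly 0 iff the study included no women and exactly 1 iff
    it included no men; proportions are never clipped onto (0, 1).
    """

    t: int
    y: float
    N: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.y <= 1.0:
            raise RecordError(f"proportion {self.y} outside [0, 1]")
        if self.N < 1:
            raise RecordError("observation without participants")


def to_observation(record: StudyRecord, window: YearWindow = DEFAULT_WINDOW) -> ProportionObservation:
    """Female proportion n/N of one study as a (t, y, N) modelling observation."""
    if record.total < 1:  # unreachable for validated records; guards raw construction
        raise RecordError(f"{record.study_id}: zero total participants")
    return ProportionObservation(
        t=record.year - window.start,
        y=record.n_women / record.total,
        N=record.total,
    )


def _format_counts(counts: Mapping[str, int]) -> str:
    return ";".join(f"{cat}:{n}" for cat, n in counts.items())


def _parse_counts(text: str, line_no: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    if not text:
        return counts
    for pair in text.split(";"):
        try:
            cat, n = pair.split(":")
            counts[cat] = int(n)
        except ValueError as exc:
            raise RecordError(
                f"line {line_no}: field 'orientation_counts' malformed pair {pair!r}"
            ) from exc
    return counts


def read_studies(
    path: str | Path,
    window: YearWindow = DEFAULT_WINDOW,
    *,
    permissive: bool = False,
) -> list[StudyRecord]:
    """Read study records from the CSV interchange format, preserving row order.

    Rows with a year outside ``window`` raise unless ``permissive`` is set,
    in which case they are skipped with a logged warning. Malformed rows
    always raise, naming the line number and offending field.
    """
    path = Path(path)
    records: list[StudyRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordError(f"{path}: empty file, expected header {','.join(CSV_HEADER)}")
        if tuple(header) != CSV_HEADER:
            raise RecordError(f"{path}: bad header {header!r}, expected {list(CSV_HEADER)}")
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not cell for cell in row):
                continue
            if len(row) != len(CSV_HEADER):
                raise RecordError(f"line {line_no}: expected {len(CSV_HEADER)} fields, got {len(row)}")
            raw = dict(zip(CSV_HEADER, row))
            for int_field in ("year", "n_women", "n_men"):
                try:
                    raw[int_field] = int(raw[int_field])
                except ValueError as exc:
                    raise RecordError(
                        f"line {line_no}: field {int_field!r} is not an integer: {raw[int_field]!r}"
                    ) from exc
            if raw["year"] not in window:
                if permissive:
                    logger.warning(
                        "line %d: year %d outside window %d-%d, row skipped",
                        line_no, raw["year"], window.start, window.end,
                    )
                    continue
                raise RecordError(
                    f"line {line_no}: field 'year' value {raw['year']} outside "
                    f"window {window.start}-{window.end}"
                )
            try:
                record = StudyRecord(
                    study_id=raw["study_id"],
                    year=raw["year"],
                    n_women=raw["n_women"],
                    n_men=raw["n_men"],
                    orientation_reported=raw["orientation_reported"],
                    orientation_counts=_parse_counts(raw["orientation_counts"], line_no),
                    phase_reported=raw["phase_reported"],
                    phase_label=raw["phase_label"] or None,
                )
            except RecordError as exc:
                raise RecordError(f"line {line_no}: {exc}") from exc
            records.append(record)
    return records


def write_studies(records: Iterable[StudyRecord], path: str | Path) -> Path:
    """Write records to CSV; ``read_studies`` round-trips the output exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.study_id,
                    rec.year,
                    rec.n_women,
                    rec.n_men,
                    rec.orientation_reported,
                    _format_counts(rec.orientation_counts),
                    rec.phase_reported,
                    rec.phase_label or "",
                ]
            )
    return path
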
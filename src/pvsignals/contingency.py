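"""2x2 contingency tables for drug--event pairs.

For a drug D and an event preferred term E, the four cells count *reports*:

=====  ============================================
a      reports with D as primary suspect and E
b      reports with D as primary suspect, without E
c      reports with E whose primary suspect is not D
d      reports with neither
=====  ============================================

so that ``a+b+c+d`` always equals the report total.  Only the
primary-suspect role enters the drug margin; the event margin ``n_event``
counts every report carrying the term regardless of drug roles.  A report
listing several distinct primary-suspect drugs contributes to each drug's
table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

from .errors import ValidationError
from .report_store import ReportSet, normalize_term

__all__ = ["ContingencyTable", "EventCounts", "build_table", "count_event_pairs",
           "write_margins", "read_margins"]


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    drug: str
    event_pt: str
    a: int
    b: int
    c: int
    d: int

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"cell {name}={v!r} must be a non-negative integer")


def build_table(
    a: int, n_drug: int, n_event: int, n_total: int, drug: str = "", event_pt: str = ""
) -> ContingencyTable:
    """Build a table from the margins (a, n_drug, n_event, n_total).

    b = n_drug - a, c = n_event - a, d = n_total - n_drug - n_event + a.
    Raises :class:`ValidationError` naming the violated inequality.
    """
    if a > n_drug:
        raise ValidationError(f"a={a} > n_drug={n_drug}")
    if a > n_event:
        raise ValidationError(f"a={a} > n_event={n_event}")
    if n_drug + n_event - a > n_total:
        raise ValidationError(
            f"n_drug + n_event - a = {n_drug + n_event - a} > n_total={n_total}"
        )
    return ContingencyTable(
        drug=drug,
        event_pt=event_pt,
        a=a,
        b=n_drug - a,
        c=n_event - a,
        d=n_total - n_drug - n_event + a,
    )


@dataclass(frozen=True)
class EventCounts:
    """Per-drug (a, n_drug) margins for one event, plus the global margins."""

    event_pt: str
    per_drug: Mapping[str, tuple[int, int]]  # drug -> (a, n_drug)
    n_event: int
    n_total: int

    def table_for(self, drug: str) -> ContingencyTable:
        a, n_drug = self.per_drug[drug]
        return build_table(a, n_drug, self.n_event, self.n_total,
                           drug=drug, event_pt=self.event_pt)

    def tables(self) -> Iterator[ContingencyTable]:
        for drug in sorted(self.per_drug):
            yield self.table_for(drug)


def count_event_pairs(rs: ReportSet, event_pt: str) -> EventCounts:
    """Count (a, n_drug) for every primary-suspect drug in ``rs``.

    ``a`` and ``n_drug`` are report counts (a drug counted once per report
    regardless of repeated listings); ``n_event`` counts reports carrying
    the event term under any drug/role.
    """
    event = normalize_term(event_pt)
    if not event:
        raise ValidationError("event_pt must be non-empty")
    per_drug: dict[str, list[int]] = {}
    n_event = 0
    for report in rs:
        has_event = event in report.reactions
        if has_event:
            n_event += 1
        for drug in report.primary_suspects():
            cell = per_drug.setdefault(drug, [0, 0])
            cell[1] += 1
            if has_event:
                cell[0] += 1
    return EventCounts(
        event_pt=event,
        per_drug={drug: (a, n) for drug, (a, n) in per_drug.items()},
        n_event=n_event,
        n_total=len(rs),
    )


def write_margins(counts: EventCounts, path: str | Path) -> None:
    """TSV interchange of per-drug margins: columns drug, a, n_drug."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["drug", "a", "n_drug"])
        for drug in sorted(counts.per_drug):
            a, n = counts.per_drug[drug]
            w.writerow([drug, str(a), str(n)])


def read_margins(path: str | Path, event_pt: str, n_event: int, n_total: int) -> EventCounts:
    per_drug: dict[str, tuple[int, int]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            per_drug[normalize_term(row["drug"])] = (int(row["a"]), int(row["n_drug"]))
    return EventCounts(event_pt=normalize_term(event_pt), per_drug=per_drug,
                       n_event=n_event, n_total=n_total)
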
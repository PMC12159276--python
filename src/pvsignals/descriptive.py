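"""Demographic and temporal summaries of event reports.

Summarises the reports carrying one event preferred term: sex breakdown
(with percentages of event reports, 1 d.p.), mean +/- sample SD of age over
reports with a stated age, top reporting countries, and per-calendar-year
report counts.  The event share of the whole database
(100 * n_event / n_total) uses the same denominator as the signal table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .report_store import ReportSet, Sex, normalize_term

__all__ = ["DemographicSummary", "summarize", "write_summary", "write_yearly_counts",
           "plot_yearly_counts"]


@dataclass(frozen=True)
class DemographicSummary:
    event_pt: str
    n_event: int
    n_total: int
    pct_event: float          # percentage of all reports, unrounded
    n_female: int
    n_male: int
    n_unknown: int
    pct_female: float         # percentages of event reports, 1 d.p.
    pct_male: float
    pct_unknown: float
    age_mean: float | None    # years, over reports with stated age
    age_sd: float | None      # sample SD (n-1); None if fewer than 2 ages
    top_countries: tuple[tuple[str, int, float], ...] = ()
    yearly_counts: dict[int, int] = field(default_factory=dict)


def summarize(
    rs: ReportSet, event_pt: str, n_total: int | None = None, top_n_countries: int = 5
) -> DemographicSummary:
    """Summarize the reports in ``rs`` that carry ``event_pt``.

    ``n_total`` defaults to ``len(rs)``; pass it explicitly when ``rs``
    holds only the event reports of a larger database (e.g. a
    margin-reconstructed set materialized without its filler reports).
    """
    if len(rs) == 0:
        raise ValidationError("summarize requires a non-empty report set")
    event = normalize_term(event_pt)
    total = len(rs) if n_total is None else n_total
    event_reports = [r for r in rs if event in r.reactions]
    n_event = len(event_reports)

    sex_counts = {Sex.FEMALE: 0, Sex.MALE: 0, Sex.UNKNOWN: 0}
    ages: list[float] = []
    countries: dict[str, int] = {}
    years: dict[int, int] = {}
    for r in event_reports:
        sex_counts[r.sex] += 1
        if r.age_years is not None:
            ages.append(r.age_years)
        if r.country:
            countries[r.country] = countries.get(r.country, 0) + 1
        if r.year is not None:
            years[r.year] = years.get(r.year, 0) + 1

    def pct(n: int) -> float:
        return round(100.0 * n / n_event, 1) if n_event else 0.0

    age_arr = np.asarray(ages, dtype=float)
    top = sorted(countries.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n_countries]
    return DemographicSummary(
        event_pt=event,
        n_event=n_event,
        n_total=total,
        pct_event=100.0 * n_event / total,
        n_female=sex_counts[Sex.FEMALE],
        n_male=sex_counts[Sex.MALE],
        n_unknown=sex_counts[Sex.UNKNOWN],
        pct_female=pct(sex_counts[Sex.FEMALE]),
        pct_male=pct(sex_counts[Sex.MALE]),
        pct_unknown=pct(sex_counts[Sex.UNKNOWN]),
        age_mean=float(age_arr.mean()) if age_arr.size else None,
        age_sd=float(age_arr.std(ddof=1)) if age_arr.size > 1 else None,
        top_countries=tuple((c, n, pct(n)) for c, n in top),
        yearly_counts=dict(sorted(years.items())),
    )


def write_summary(s: DemographicSummary, path: str | Path) -> None:
    rows = [
        ("event_pt", s.event_pt),
        ("n_event", s.n_event),
        ("n_total", s.n_total),
        ("pct_event", f"{s.pct_event:.2f}"),
        ("n_female", s.n_female),
        ("pct_female", f"{s.pct_female:.1f}"),
        ("n_male", s.n_male),
        ("pct_male", f"{s.pct_male:.1f}"),
        ("n_unknown", s.n_unknown),
        ("pct_unknown", f"{s.pct_unknown:.1f}"),
        ("age_mean", "" if s.age_mean is None else f"{s.age_mean:.1f}"),
        ("age_sd", "" if s.age_sd is None else f"{s.age_sd:.1f}"),
    ]
    rows += [(f"country:{c}", f"{n} ({p:.1f})") for c, n, p in s.top_countries]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["field", "value"])
        w.writerows(rows)


def write_yearly_counts(s: DemographicSummary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["year", "n_reports"])
        for year, n in s.yearly_counts.items():
            w.writerow([year, n])


def plot_yearly_counts(s: DemographicSummary, path: str | Path) -> None:
    """Bar chart of per-year event report counts (no smoothing)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    years = list(s.yearly_counts)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(years, [s.yearly_counts[y] for y in years], color="#4878a8")
    ax.set_xlabel("year")
    ax.set_ylabel("reports")
    ax.set_title(f"{s.event_pt}: reports per year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
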
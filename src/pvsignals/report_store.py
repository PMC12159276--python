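"""Typed in-memory model of a spontaneous-report database.

A spontaneous reporting system (FAERS and its relatives) stores one *case
report* per suspected adverse event occurrence: demographics, the list of
drugs on the report with their role codes (primary suspect, secondary
suspect, concomitant, interacting), and the reactions coded as MedDRA-style
preferred terms.  This module defines the :class:`AEReport` /
:class:`ReportSet` containers plus readers and writers for a FAERS-style
delimited dialect (separate DEMO / DRUG / REAC tables, or a flat one-row-per
(report, drug, reaction) table used in tests).

The counting unit throughout the package is the report: a drug--event pair
is counted at most once per report even if the pair is listed repeatedly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import DialectError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "DrugRole",
    "AEReport",
    "ReportSet",
    "normalize_term",
    "read_reports",
    "write_reports",
    "read_flat",
    "write_flat",
]


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"
    UNKNOWN = "UNK"


class DrugRole(str, Enum):
    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"


#: days / months per year used when converting reported ages
_AGE_UNIT_TO_YEARS = {"YR": 1.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25}

MAX_AGE_YEARS = 130.0


def normalize_term(name: str) -> str:
    """Normalize a drug name or preferred term.

    Trims surrounding whitespace, case-folds, and collapses internal runs
    of whitespace to single spaces.  No synonym mapping is applied: distinct
    trade/generic spellings (e.g. "alendronate" vs "alendronic acid")
    remain distinct terms, as they do in the source database.  Idempotent.
    """
    return " ".join(name.split()).casefold()


@dataclass(slots=True)
class AEReport:
    """One spontaneous adverse-event report (one FAERS-style case)."""

    report_id: str
    sex: Sex = Sex.UNKNOWN
    age_years: float | None = None
    country: str | None = None
    year: int | None = None
    #: ordered (drug_name, role) pairs; names are stored normalized
    drugs: tuple[tuple[str, DrugRole], ...] = ()
    #: normalized preferred terms
    reactions: frozenset[str] = frozenset()

    def validate(self) -> None:
        if not self.report_id:
            raise ValidationError("report_id must be non-empty")
        if not self.drugs:
            raise ValidationError(f"report {self.report_id}: drugs must be non-empty")
        if not self.reactions:
            raise ValidationError(f"report {self.report_id}: reactions must be non-empty")
        if self.age_years is not None and not (0.0 <= self.age_years <= MAX_AGE_YEARS):
            raise ValidationError(
                f"report {self.report_id}: age_years {self.age_years!r} outside [0, {MAX_AGE_YEARS}]"
            )

    def primary_suspects(self) -> set[str]:
        return {d for d, role in self.drugs if role is DrugRole.PRIMARY_SUSPECT}


@dataclass
class ReportSet:
    """A collection of unique :class:`AEReport` objects."""

    reports: list[AEReport] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate report_id values: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[AEReport]:
        return iter(self.reports)

    def validate(self) -> None:
        for r in self.reports:
            r.validate()


# ---------------------------------------------------------------------------
# Delimited dialects
# ---------------------------------------------------------------------------

DEMO_COLUMNS = ["report_id", "sex", "age", "age_unit", "country", "event_year"]
DRUG_COLUMNS = ["report_id", "drug_seq", "drug_name", "role_cod"]
REAC_COLUMNS = ["report_id", "pt"]
FLAT_COLUMNS = ["report_id", "sex", "age", "country", "year", "drug_name", "role_cod", "pt"]

_SEX_IN = {"F": Sex.FEMALE, "M": Sex.MALE, "UNK": Sex.UNKNOWN, "": Sex.UNKNOWN}
_ROLE_IN = {r.value: r for r in DrugRole}


def _sniff_sep(path: Path) -> str:
    """FAERS extracts use '$'-delimited ASCII; tests mostly use TSV."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "$" if "$" in header else "\t"


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing mandatory column(s) {missing}")
    return df


def _parse_age(age: str, unit: str) -> float | None:
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    factor = _AGE_UNIT_TO_YEARS.get(unit.upper() or "YR")
    if factor is None:
        return None
    years = value * factor
    return years if 0.0 <= years <= MAX_AGE_YEARS else None


def _parse_year(raw: str) -> int | None:
    try:
        return int(raw)
    except (TypeError, ValueError):
        return None


def read_reports(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    dialect: str = "three_table",
) -> ReportSet:
    """Read a report database from the three-table dialect.

    Rows with an empty/unparseable ``report_id`` are dropped (count logged).
    DRUG/REAC rows referencing a report absent from DEMO are orphans and are
    dropped with a warning.  Duplicate DEMO rows with conflicting
    demographics raise :class:`ValidationError`; exact duplicates collapse.
    Reports that end up with no drugs or no reactions are dropped (logged),
    since they violate the data model.
    """
    if dialect != "three_table":
        raise DialectError(f"unknown dialect {dialect!r}; use read_flat for the flat dialect")
    demo = _read_table(Path(demo_path), DEMO_COLUMNS)
    drug = _read_table(Path(drug_path), DRUG_COLUMNS)
    reac = _read_table(Path(reac_path), REAC_COLUMNS)

    n_bad_id = int((demo["report_id"].str.strip() == "").sum())
    if n_bad_id:
        logger.info("dropped %d DEMO rows with unparseable report_id", n_bad_id)
        demo = demo[demo["report_id"].str.strip() != ""]

    # conflicting duplicate demographics are a hard error; exact dupes collapse
    dup_mask = demo["report_id"].duplicated(keep=False)
    if dup_mask.any():
        dupes = demo[dup_mask]
        conflicting = sorted(
            rid
            for rid, grp in dupes.groupby("report_id")
            if len(grp.drop_duplicates()) > 1
        )
        if conflicting:
            raise ValidationError(
                f"duplicate report_id with conflicting demographics: {conflicting[:10]}"
            )
        demo = demo.drop_duplicates(subset="report_id")

    known = set(demo["report_id"])

    drugs_by_id: dict[str, list[tuple[int, str, DrugRole]]] = {rid: [] for rid in known}
    n_orphan_drug = 0
    for rid, seq, name, role in drug[DRUG_COLUMNS].itertuples(index=False):
        if rid not in drugs_by_id:
            n_orphan_drug += 1
            continue
        norm = normalize_term(name)
        role_enum = _ROLE_IN.get(role.strip().upper())
        if not norm or role_enum is None:
            n_orphan_drug += 1
            continue
        try:
            seq_i = int(seq)
        except ValueError:
            seq_i = 0
        drugs_by_id[rid].append((seq_i, norm, role_enum))
    if n_orphan_drug:
        logger.warning("dropped %d orphan/invalid DRUG rows", n_orphan_drug)

    reac_by_id: dict[str, set[str]] = {rid: set() for rid in known}
    n_orphan_reac = 0
    for rid, pt in reac[REAC_COLUMNS].itertuples(index=False):
        norm = normalize_term(pt)
        if rid not in reac_by_id or not norm:
            n_orphan_reac += 1
            continue
        reac_by_id[rid].add(norm)
    if n_orphan_reac:
        logger.warning("dropped %d orphan/invalid REAC rows", n_orphan_reac)

    reports: list[AEReport] = []
    n_incomplete = 0
    for rid, sex, age, age_unit, country, event_year in demo[DEMO_COLUMNS].itertuples(index=False):
        drug_list = sorted(drugs_by_id[rid])
        reactions = reac_by_id[rid]
        if not drug_list or not reactions:
            n_incomplete += 1
            continue
        reports.append(
            AEReport(
                report_id=rid,
                sex=_SEX_IN.get(sex.strip().upper(), Sex.UNKNOWN),
                age_years=_parse_age(age, age_unit),
                country=country.strip() or None,
                year=_parse_year(event_year),
                drugs=tuple((name, role) for _, name, role in drug_list),
                reactions=frozenset(reactions),
            )
        )
    if n_incomplete:
        logger.warning("dropped %d reports with no drug or no reaction rows", n_incomplete)
    return ReportSet(reports, provenance=f"read:{demo_path}")


def _fmt_age(age: float | None) -> str:
    if age is None:
        return ""
    return f"{age:g}"


def write_reports(
    rs: ReportSet,
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    sep: str = "\t",
) -> None:
    """Write the three-table dialect; ``read_reports`` inverts it exactly.

    Output is byte-stable: fixed column order, reports in stored order,
    reactions sorted lexicographically, ages always written in years.
    """
    with open(demo_path, "w", encoding="utf-8", newline="") as fd, open(
        drug_path, "w", encoding="utf-8", newline=""
    ) as fg, open(reac_path, "w", encoding="utf-8", newline="") as fr:
        wd = csv.writer(fd, delimiter=sep, lineterminator="\n")
        wg = csv.writer(fg, delimiter=sep, lineterminator="\n")
        wr = csv.writer(fr, delimiter=sep, lineterminator="\n")
        wd.writerow(DEMO_COLUMNS)
        wg.writerow(DRUG_COLUMNS)
        wr.writerow(REAC_COLUMNS)
        for r in rs:
            wd.writerow(
                [
                    r.report_id,
                    r.sex.value,
                    _fmt_age(r.age_years),
                    "YR" if r.age_years is not None else "",
                    r.country or "",
                    "" if r.year is None else str(r.year),
                ]
            )
            for seq, (name, role) in enumerate(r.drugs, start=1):
                wg.writerow([r.report_id, str(seq), name, role.value])
            for pt in sorted(r.reactions):
                wr.writerow([r.report_id, pt])


# ---------------------------------------------------------------------------
# Flat dialect (one row per report x drug x reaction), convenient for tests
# ---------------------------------------------------------------------------


def write_flat(rs: ReportSet, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(FLAT_COLUMNS)
        for r in rs:
            for name, role in r.drugs:
                for pt in sorted(r.reactions):
                    w.writerow(
                        [
                            r.report_id,
                            r.sex.value,
                            _fmt_age(r.age_years),
                            r.country or "",
                            "" if r.year is None else str(r.year),
                            name,
                            role.value,
                            pt,
                        ]
                    )


def read_flat(path: str | Path) -> ReportSet:
    df = _read_table(Path(path), FLAT_COLUMNS)
    df = df[df["report_id"].str.strip() != ""]
    reports: list[AEReport] = []
    for rid, grp in df.groupby("report_id", sort=False):
        first = grp.iloc[0]
        drug_pairs: list[tuple[str, DrugRole]] = []
        seen: set[tuple[str, DrugRole]] = set()
        for name, role in zip(grp["drug_name"], grp["role_cod"]):
            pair = (normalize_term(name), _ROLE_IN[role.strip().upper()])
            if pair not in seen:
                seen.add(pair)
                drug_pairs.append(pair)
        reports.append(
            AEReport(
                report_id=str(rid),
                sex=_SEX_IN.get(first["sex"].strip().upper(), Sex.UNKNOWN),
                age_years=_parse_age(first["age"], "YR"),
                country=first["country"].strip() or None,
                year=_parse_year(first["year"]),
                drugs=tuple(drug_pairs),
                reactions=frozenset(normalize_term(p) for p in grp["pt"] if normalize_term(p)),
            )
        )
    return ReportSet(reports, provenance=f"read_flat:{path}")
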
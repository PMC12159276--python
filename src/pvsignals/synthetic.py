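"""Synthetic spontaneous-report generators.

Two complementary generators:

* :func:`reconstruct_from_margins` -- given a :class:`MarginSpec` (an event
  term, the database totals, and per-drug ``(a, n_drug)`` margins), build a
  report set whose 2x2 tables reproduce those margins *exactly*, cell by
  cell.  Each synthetic report carries exactly one primary-suspect drug and
  one reaction (the event or a filler term).  Demographics, when requested,
  are assigned to the event reports so that sex/country counts match
  exactly and ages match the requested mean/SD approximately (seeded
  draws).  The packaged fixture (:func:`load_cts_fixture`) encodes the
  drug--carpal-tunnel-syndrome margin set used throughout the test suite.

* :func:`simulate_reports` -- a stochastic generator: every report draws a
  primary-suspect drug from a catalogue of marginal probabilities and the
  event occurs with a background probability, raised for injected drugs so
  that the expected odds ratio against all other drugs equals a requested
  ``target_ror``.  Used for parameter-recovery experiments.  The random
  draws are made once, at the margin level (one multinomial over the drug
  catalogue, then one binomial per drug), and reports are materialized
  deterministically from those counts -- distributionally identical to
  per-report sampling and exactly consistent with the fast margin-only path
  :func:`simulate_margins`.

Large reconstructions (the full-database scale is ~1.3e7 reports) should
not be materialized in memory: :func:`stream_reconstruction` writes the
three report tables directly to disk, and :func:`scale_margin_spec`
down-scales a spec with largest-remainder rounding so that small,
margin-consistent sets can be materialized for tests.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .contingency import EventCounts
from .errors import InfeasibleMarginsError
from .report_store import AEReport, DrugRole, ReportSet, Sex, normalize_term, write_reports

__all__ = [
    "DrugMargin",
    "Demographics",
    "MarginSpec",
    "SimulationSpec",
    "margin_counts",
    "reconstruct_from_margins",
    "stream_reconstruction",
    "scale_margin_spec",
    "simulate_margins",
    "simulate_reports",
    "load_margin_spec",
    "save_margin_spec",
    "load_cts_fixture",
]

DEFAULT_FILLER_DRUG = "other suspect drug"
DEFAULT_FILLER_REACTION = "drug ineffective"


class DrugMargin(BaseModel):
    drug: str
    a: int = Field(ge=0)
    n_drug: int = Field(ge=0)


class Demographics(BaseModel):
    """Demographic targets for the event reports of a reconstruction."""

    n_female: int = Field(ge=0)
    n_male: int = Field(ge=0)
    n_unknown: int = Field(default=0, ge=0)
    age_mean: float = Field(gt=0)
    age_sd: float = Field(gt=0)
    countries: dict[str, int] = Field(default_factory=dict)
    year_start: int = 2004
    year_end: int = 2024

    @model_validator(mode="after")
    def _check(self) -> "Demographics":
        if self.year_end < self.year_start:
            raise ValueError("year_end < year_start")
        if any(v < 0 for v in self.countries.values()):
            raise ValueError("country counts must be non-negative")
        return self


class MarginSpec(BaseModel):
    """Exact margins for a reconstruction; infeasible specs are rejected."""

    event_pt: str
    n_total: int = Field(gt=0)
    n_event: int = Field(ge=0)
    drugs: list[DrugMargin]
    filler_drug_name: str = DEFAULT_FILLER_DRUG
    filler_reaction: str = DEFAULT_FILLER_REACTION
    demographics: Demographics | None = None

    @model_validator(mode="after")
    def _check(self) -> "MarginSpec":
        for dm in self.drugs:
            if dm.a > dm.n_drug:
                raise InfeasibleMarginsError(f"{dm.drug}: a={dm.a} > n_drug={dm.n_drug}")
        names = [normalize_term(dm.drug) for dm in self.drugs]
        if len(set(names)) != len(names):
            raise InfeasibleMarginsError("duplicate drug names in margin list")
        if normalize_term(self.filler_drug_name) in names:
            raise InfeasibleMarginsError("filler drug collides with a listed drug")
        if normalize_term(self.filler_reaction) == normalize_term(self.event_pt):
            raise InfeasibleMarginsError("filler reaction must differ from the event term")
        sum_n = sum(dm.n_drug for dm in self.drugs)
        sum_a = sum(dm.a for dm in self.drugs)
        if sum_n > self.n_total:
            raise InfeasibleMarginsError(f"sum n_drug={sum_n} > n_total={self.n_total}")
        if sum_a > self.n_event:
            raise InfeasibleMarginsError(f"sum a={sum_a} > n_event={self.n_event}")
        if self.n_event > self.n_total:
            raise InfeasibleMarginsError(f"n_event={self.n_event} > n_total={self.n_total}")
        # filler event reports may not exceed filler reports
        if self.n_event - sum_a > self.n_total - sum_n:
            raise InfeasibleMarginsError(
                f"n_event - sum a = {self.n_event - sum_a} exceeds the "
                f"{self.n_total - sum_n} reports left for the filler drug"
            )
        d = self.demographics
        if d is not None:
            if d.n_female + d.n_male + d.n_unknown != self.n_event:
                raise InfeasibleMarginsError(
                    f"sex counts sum to {d.n_female + d.n_male + d.n_unknown}, "
                    f"expected n_event={self.n_event}"
                )
            if sum(d.countries.values()) > self.n_event:
                raise InfeasibleMarginsError("country counts exceed n_event")
        return self


# ---------------------------------------------------------------------------
# Exact-margin reconstruction
# ---------------------------------------------------------------------------


def margin_counts(spec: MarginSpec) -> EventCounts:
    """The per-drug margin set a reconstruction realises, without
    materializing any report (the filler drug absorbs the remainder)."""
    per_drug = {normalize_term(dm.drug): (dm.a, dm.n_drug) for dm in spec.drugs}
    sum_a = sum(dm.a for dm in spec.drugs)
    sum_n = sum(dm.n_drug for dm in spec.drugs)
    per_drug[normalize_term(spec.filler_drug_name)] = (
        spec.n_event - sum_a,
        spec.n_total - sum_n,
    )
    return EventCounts(
        event_pt=normalize_term(spec.event_pt),
        per_drug=per_drug,
        n_event=spec.n_event,
        n_total=spec.n_total,
    )


def _event_attributes(spec: MarginSpec, rng: np.random.Generator):
    """Seeded per-event-report demographic attributes matching the spec."""
    d = spec.demographics
    n = spec.n_event
    if d is None:
        return None
    sexes = np.array(
        [Sex.FEMALE] * d.n_female + [Sex.MALE] * d.n_male + [Sex.UNKNOWN] * d.n_unknown,
        dtype=object,
    )
    rng.shuffle(sexes)
    countries: list[str | None] = []
    for country, count in d.countries.items():
        countries.extend([country] * count)
    countries.extend([None] * (n - len(countries)))
    countries_arr = np.array(countries, dtype=object)
    rng.shuffle(countries_arr)
    ages = np.clip(rng.normal(d.age_mean, d.age_sd, size=n), 0.0, 130.0)
    years = rng.integers(d.year_start, d.year_end + 1, size=n)
    return sexes, countries_arr, ages, years


def _iter_reconstructed(
    spec: MarginSpec, seed: int, include_filler: bool
) -> Iterator[AEReport]:
    rng = np.random.default_rng(seed)
    attrs = _event_attributes(spec, rng)
    event = normalize_term(spec.event_pt)
    filler_pt = normalize_term(spec.filler_reaction)
    fs_event = frozenset({event})
    fs_filler = frozenset({filler_pt})

    rows: list[tuple[str, int, int]] = [
        (normalize_term(dm.drug), dm.a, dm.n_drug) for dm in spec.drugs
    ]
    sum_a = sum(a for _, a, _ in rows)
    sum_n = sum(n for _, _, n in rows)
    rows.append(
        (normalize_term(spec.filler_drug_name), spec.n_event - sum_a, spec.n_total - sum_n)
    )

    idx = 0       # running report index (ids stay stable with/without filler)
    ev_idx = 0    # running event-report index into the demographic arrays
    for drug, a, n_drug in rows:
        drug_key = (( drug, DrugRole.PRIMARY_SUSPECT),)
        for j in range(n_drug):
            is_event = j < a
            if not is_event and not include_filler:
                idx += n_drug - j
                break
            rid = f"R{idx:09d}"
            idx += 1
            if is_event and attrs is not None:
                sexes, countries, ages, years = attrs
                report = AEReport(
                    report_id=rid,
                    sex=sexes[ev_idx],
                    age_years=float(ages[ev_idx]),
                    country=countries[ev_idx],
                    year=int(years[ev_idx]),
                    drugs=drug_key,
                    reactions=fs_event,
                )
                ev_idx += 1
            else:
                report = AEReport(
                    report_id=rid,
                    drugs=drug_key,
                    reactions=fs_event if is_event else fs_filler,
                )
                if is_event:
                    ev_idx += 1
            yield report


def reconstruct_from_margins(
    spec: MarginSpec, seed: int = 0, include_filler: bool = True
) -> ReportSet:
    """Materialize a report set realising the spec's margins exactly.

    With ``include_filler=False`` only the ``n_event`` event-carrying
    reports are materialized (the filler reports contain no demographic or
    per-drug information beyond their counts); pass ``spec.n_total`` to
    :func:`pvsignals.descriptive.summarize` in that case.  Sets at full
    database scale should use :func:`stream_reconstruction` instead.
    """
    reports = list(_iter_reconstructed(spec, seed, include_filler))
    return ReportSet(reports, provenance=f"reconstructed:{spec.event_pt}")


def stream_reconstruction(
    spec: MarginSpec,
    seed: int,
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    chunk_size: int = 100_000,
) -> int:
    """Write a reconstruction straight to the three report tables.

    Holds at most ``chunk_size`` reports in memory; returns the number of
    reports written.  Output is identical to ``write_reports`` of the fully
    materialized set.
    """
    import csv
    from .report_store import DEMO_COLUMNS, DRUG_COLUMNS, REAC_COLUMNS, _fmt_age

    n = 0
    with open(demo_path, "w", encoding="utf-8", newline="") as fd, open(
        drug_path, "w", encoding="utf-8", newline=""
    ) as fg, open(reac_path, "w", encoding="utf-8", newline="") as fr:
        wd = csv.writer(fd, delimiter="\t", lineterminator="\n")
        wg = csv.writer(fg, delimiter="\t", lineterminator="\n")
        wr = csv.writer(fr, delimiter="\t", lineterminator="\n")
        wd.writerow(DEMO_COLUMNS)
        wg.writerow(DRUG_COLUMNS)
        wr.writerow(REAC_COLUMNS)
        for r in _iter_reconstructed(spec, seed, include_filler=True):
            wd.writerow([
                r.report_id, r.sex.value, _fmt_age(r.age_years),
                "YR" if r.age_years is not None else "",
                r.country or "", "" if r.year is None else str(r.year),
            ])
            name, role = r.drugs[0]
            wg.writerow([r.report_id, "1", name, role.value])
            wr.writerow([r.report_id, next(iter(r.reactions))])
            n += 1
    return n


# ---------------------------------------------------------------------------
# Down-scaling
# ---------------------------------------------------------------------------


def _largest_remainder(quotas: list[float], target: int) -> list[int]:
    """Integer apportionment of ``target`` by the largest-remainder rule."""
    floors = [math.floor(q) for q in quotas]
    short = target - sum(floors)
    if short < 0:
        raise InfeasibleMarginsError("scaling target below the sum of floors")
    order = sorted(range(len(quotas)), key=lambda i: (floors[i] - quotas[i], i))
    out = floors[:]
    for i in order[:short]:
        out[i] += 1
    return out


def scale_margin_spec(spec: MarginSpec, factor: float) -> MarginSpec:
    """Divide every count by ``factor``, keeping margins mutually consistent.

    Uses largest-remainder rounding so that the scaled per-drug event counts
    still sum to the scaled event total and the per-drug report counts to
    the scaled database total.  Demographic counts scale with the event
    total.  Raises if the scaled spec is infeasible.
    """
    if factor <= 0:
        raise InfeasibleMarginsError("scale factor must be positive")
    k = len(spec.drugs)
    sum_a = sum(dm.a for dm in spec.drugs)
    sum_n = sum(dm.n_drug for dm in spec.drugs)
    n_total_s = max(1, round(spec.n_total / factor))
    n_event_s = max(1, round(spec.n_event / factor)) if spec.n_event else 0

    a_quotas = [dm.a / factor for dm in spec.drugs] + [(spec.n_event - sum_a) / factor]
    a_scaled = _largest_remainder(a_quotas, n_event_s)
    n_quotas = [dm.n_drug / factor for dm in spec.drugs] + [(spec.n_total - sum_n) / factor]
    n_scaled = _largest_remainder(n_quotas, n_total_s)
    # a drug's scaled event count may not exceed its scaled report count
    for i in range(k):
        if a_scaled[i] > n_scaled[i]:
            deficit = a_scaled[i] - n_scaled[i]
            n_scaled[i] += deficit
            n_scaled[k] -= deficit
    if n_scaled[k] < a_scaled[k]:
        raise InfeasibleMarginsError("scaled filler margins infeasible; use a smaller factor")

    demo = None
    if spec.demographics is not None:
        d = spec.demographics
        sex_scaled = _largest_remainder(
            [d.n_female / factor, d.n_male / factor, d.n_unknown / factor], n_event_s
        )
        total_country = sum(d.countries.values())
        country_target = min(n_event_s, round(total_country / factor))
        names = list(d.countries)
        c_scaled = _largest_remainder([d.countries[c] / factor for c in names], country_target)
        demo = Demographics(
            n_female=sex_scaled[0], n_male=sex_scaled[1], n_unknown=sex_scaled[2],
            age_mean=d.age_mean, age_sd=d.age_sd,
            countries={c: v for c, v in zip(names, c_scaled) if v},
            year_start=d.year_start, year_end=d.year_end,
        )
    return MarginSpec(
        event_pt=spec.event_pt,
        n_total=n_total_s,
        n_event=n_event_s,
        drugs=[
            DrugMargin(drug=dm.drug, a=a_scaled[i], n_drug=n_scaled[i])
            for i, dm in enumerate(spec.drugs)
        ],
        filler_drug_name=spec.filler_drug_name,
        filler_reaction=spec.filler_reaction,
        demographics=demo,
    )


# ---------------------------------------------------------------------------
# Stochastic simulation with injected associations
# ---------------------------------------------------------------------------


class SimulationSpec(BaseModel):
    """Stochastic report-database model with injected drug--event signals.

    Each report receives one primary-suspect drug (catalogue probabilities;
    the remaining mass goes to a filler drug) and the event with probability
    ``background_p``, raised for injected drugs so the expected reporting
    odds ratio against all other drugs equals ``target_ror``.
    """

    n_reports: int = Field(gt=0)
    drugs: dict[str, float]
    background_p: float = Field(gt=0, lt=1)
    injected: dict[str, float] = Field(default_factory=dict)
    event_pt: str = "carpal tunnel syndrome"
    filler_drug_name: str = DEFAULT_FILLER_DRUG
    filler_reaction: str = DEFAULT_FILLER_REACTION
    p_female: float = Field(default=0.5, ge=0, le=1)
    age_mean: float = 57.0
    age_sd: float = 15.0
    year_start: int = 2004
    year_end: int = 2024
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationSpec":
        if any(not (0 < p < 1) for p in self.drugs.values()):
            raise ValueError("drug marginal probabilities must lie in (0,1)")
        if sum(self.drugs.values()) >= 1:
            raise ValueError("drug marginal probabilities must sum to < 1")
        unknown = set(self.injected) - set(self.drugs)
        if unknown:
            raise ValueError(f"injected drugs not in catalogue: {sorted(unknown)}")
        if any(r <= 0 for r in self.injected.values()):
            raise ValueError("target_ror must be > 0")
        return self

    def event_probability(self, drug: str) -> float:
        """Per-report event probability for a drug, from its target odds ratio."""
        odds0 = self.background_p / (1.0 - self.background_p)
        target = self.injected.get(drug)
        if target is None:
            return self.background_p
        odds1 = target * odds0
        return odds1 / (1.0 + odds1)


def simulate_margins(spec: SimulationSpec) -> EventCounts:
    """Draw the per-drug (a, n_drug) margins of one simulated database.

    One multinomial assigns every report a primary-suspect drug; one
    binomial per drug draws its event count.  Shares the RNG stream with
    :func:`simulate_reports`, which materializes the same margins.
    """
    rng = np.random.default_rng(spec.seed)
    names = [normalize_term(d) for d in spec.drugs] + [normalize_term(spec.filler_drug_name)]
    probs = list(spec.drugs.values())
    probs.append(1.0 - sum(probs))
    counts = rng.multinomial(spec.n_reports, probs)
    per_drug: dict[str, tuple[int, int]] = {}
    n_event = 0
    for name, raw, n_d in zip(names, list(spec.drugs) + [spec.filler_drug_name], counts):
        a = int(rng.binomial(n_d, spec.event_probability(raw))) if n_d else 0
        per_drug[name] = (a, int(n_d))
        n_event += a
    return EventCounts(
        event_pt=normalize_term(spec.event_pt),
        per_drug=per_drug,
        n_event=n_event,
        n_total=spec.n_reports,
    )


def simulate_reports(spec: SimulationSpec) -> ReportSet:
    """Materialize a full simulated report set (reproducible from the seed)."""
    counts = simulate_margins(spec)
    rng = np.random.default_rng((spec.seed, 1))
    n = spec.n_reports
    sexes = rng.random(n) < spec.p_female
    ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 0.0, 130.0)
    years = rng.integers(spec.year_start, spec.year_end + 1, size=n)

    event = counts.event_pt
    fs_event = frozenset({event})
    fs_filler = frozenset({normalize_term(spec.filler_reaction)})
    reports: list[AEReport] = []
    idx = 0
    for drug in counts.per_drug:
        a, n_drug = counts.per_drug[drug]
        drug_key = ((drug, DrugRole.PRIMARY_SUSPECT),)
        for j in range(n_drug):
            reports.append(
                AEReport(
                    report_id=f"S{idx:09d}",
                    sex=Sex.FEMALE if sexes[idx] else Sex.MALE,
                    age_years=float(ages[idx]),
                    year=int(years[idx]),
                    drugs=drug_key,
                    reactions=fs_event if j < a else fs_filler,
                )
            )
            idx += 1
    return ReportSet(reports, provenance=f"simulated:seed={spec.seed}")


# ---------------------------------------------------------------------------
# Spec files
# ---------------------------------------------------------------------------


def save_margin_spec(spec: MarginSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec.model_dump(), fh, sort_keys=False)


def load_margin_spec(path: str | Path) -> MarginSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return MarginSpec.model_validate(yaml.safe_load(fh))


def load_simulation_spec(path: str | Path) -> SimulationSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return SimulationSpec.model_validate(yaml.safe_load(fh))


def load_cts_fixture() -> MarginSpec:
    """The packaged drug--carpal-tunnel-syndrome margin fixture."""
    from importlib.resources import files

    path = files("pvsignals.data").joinpath("cts_faers_margins.yaml")
    return MarginSpec.model_validate(yaml.safe_load(path.read_text(encoding="utf-8")))
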
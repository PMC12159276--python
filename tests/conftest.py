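import numpy as np
import pytest

from pvsignals import AEReport, DrugRole, ReportSet, Sex, load_cts_fixture


def make_report(rid, drugs, reactions, sex=Sex.UNKNOWN, age=None, country=None, year=None):
    """Compact report builder: drugs as [(name, role)], reactions as strings."""
    return AEReport(
        report_id=rid,
        sex=sex,
        age_years=age,
        country=country,
        year=year,
        drugs=tuple((n, r) for n, r in drugs),
        reactions=frozenset(reactions),
    )


PS = DrugRole.PRIMARY_SUSPECT
SS = DrugRole.SECONDARY_SUSPECT
CO = DrugRole.CONCOMITANT


@pytest.fixture(scope="session")
def cts_spec():
    return load_cts_fixture()


@pytest.fixture
def small_reportset():
    """Two well-formed reports exercising demographics, roles, reactions."""
    return ReportSet(
        [
            make_report(
                "r1", [("drug x", PS), ("drug y", CO)], ["headache", "nausea"],
                sex=Sex.FEMALE, age=63.0, country="US", year=2019,
            ),
            make_report(
                "r2", [("drug y", PS)], ["carpal tunnel syndrome"],
                sex=Sex.MALE, age=41.5, country="CA", year=2021,
            ),
        ],
        provenance="fixture",
    )


def random_reportset(rng: np.random.Generator, n_reports: int, event="evt") -> ReportSet:
    """Messy random report set: multiple drugs/roles/reactions per report,
    repeated drug listings, occasional multiple primary suspects."""
    drug_pool = [f"drug{i}" for i in range(6)]
    roles = list(DrugRole)
    reports = []
    for i in range(n_reports):
        k = rng.integers(1, 4)
        drugs = tuple(
            (drug_pool[rng.integers(len(drug_pool))], roles[rng.integers(len(roles))])
            for _ in range(k)
        )
        reactions = {event} if rng.random() < 0.3 else {"other"}
        if rng.random() < 0.2:
            reactions.add("extra term")
        reports.append(make_report(f"x{i}", drugs, reactions))
    return ReportSet(reports)
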
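"""Exact-margin reconstruction and stochastic simulation."""

import numpy as np
import pytest

from pvsignals import (
    MarginSpec,
    SimulationSpec,
    count_event_pairs,
    margin_counts,
    read_reports,
    reconstruct_from_margins,
    ror,
    scale_margin_spec,
    simulate_margins,
    simulate_reports,
    stream_reconstruction,
    summarize,
    write_reports,
)
from pvsignals.errors import InfeasibleMarginsError
from pvsignals.synthetic import DrugMargin, load_margin_spec, save_margin_spec


def tiny_spec(**overrides):
    base = dict(
        event_pt="evt",
        n_total=200,
        n_event=30,
        drugs=[
            DrugMargin(drug="alpha", a=12, n_drug=40),
            DrugMargin(drug="beta", a=3, n_drug=25),
        ],
    )
    base.update(overrides)
    return MarginSpec(**base)


def test_reconstruction_realises_margins_cell_by_cell():
    spec = tiny_spec()
    rs = reconstruct_from_margins(spec, seed=5)
    counts = count_event_pairs(rs, "evt")
    assert dict(counts.per_drug) == dict(margin_counts(spec).per_drug)
    assert counts.n_event == 30 and counts.n_total == 200


def test_single_report_degenerate_spec():
    spec = MarginSpec(
        event_pt="evt", n_total=1, n_event=1,
        drugs=[DrugMargin(drug="only", a=1, n_drug=1)],
    )
    rs = reconstruct_from_margins(spec, seed=0)
    assert len(rs) == 1
    (r,) = rs.reports
    assert "evt" in r.reactions


def test_reconstruction_roundtrips_through_report_files(tmp_path):
    spec = tiny_spec()
    rs = reconstruct_from_margins(spec, seed=5)
    paths = [tmp_path / n for n in ("demo.tsv", "drug.tsv", "reac.tsv")]
    write_reports(rs, *paths)
    back = read_reports(*paths)
    counts = count_event_pairs(back, "evt")
    assert dict(counts.per_drug) == dict(margin_counts(spec).per_drug)


def test_stream_reconstruction_matches_materialized_write(tmp_path):
    spec = tiny_spec()
    (tmp_path / "mem").mkdir()
    (tmp_path / "stream").mkdir()
    mem = [tmp_path / "mem" / n for n in ("demo.tsv", "drug.tsv", "reac.tsv")]
    streamed = [tmp_path / "stream" / n for n in ("demo.tsv", "drug.tsv", "reac.tsv")]
    write_reports(reconstruct_from_margins(spec, seed=9), *mem)
    n = stream_reconstruction(spec, 9, *streamed)
    assert n == spec.n_total
    for p1, p2 in zip(mem, streamed):
        assert p1.read_bytes() == p2.read_bytes()


def test_reconstruction_is_deterministic_per_seed(cts_spec):
    spec = scale_margin_spec(cts_spec, 1000)
    a = reconstruct_from_margins(spec, seed=3)
    b = reconstruct_from_margins(spec, seed=3)
    c = reconstruct_from_margins(spec, seed=4)
    assert a.reports == b.reports
    assert a.reports != c.reports  # demographics reshuffled


@pytest.mark.parametrize(
    "overrides,fragment",
    [
        (dict(drugs=[DrugMargin(drug="alpha", a=50, n_drug=40)]), "a=50"),
        (dict(n_event=10), "sum a"),
        (dict(n_total=60), "sum n_drug"),
        (dict(n_total=70, n_event=25), "filler"),
    ],
)
def test_infeasible_margins_cite_the_violated_inequality(overrides, fragment):
    with pytest.raises(InfeasibleMarginsError, match=fragment):
        tiny_spec(**overrides)


def test_margin_spec_yaml_roundtrip(tmp_path, cts_spec):
    path = tmp_path / "spec.yaml"
    save_margin_spec(cts_spec, path)
    assert load_margin_spec(path) == cts_spec


def test_packaged_fixture_demographics_reproduced(cts_spec):
    rs = reconstruct_from_margins(cts_spec, seed=11, include_filler=False)
    assert len(rs) == cts_spec.n_event
    s = summarize(rs, cts_spec.event_pt, n_total=cts_spec.n_total)
    d = cts_spec.demographics
    assert (s.n_female, s.n_male, s.n_unknown) == (d.n_female, d.n_male, d.n_unknown)
    assert s.age_mean == pytest.approx(d.age_mean, abs=0.5)
    assert s.age_sd == pytest.approx(d.age_sd, abs=0.5)
    assert s.top_countries[0][:2] == ("US", d.countries["US"])


def test_scaling_preserves_margin_consistency(cts_spec):
    for factor in (10, 100, 1000):
        scaled = scale_margin_spec(cts_spec, factor)
        counts = margin_counts(scaled)  # construction re-validates feasibility
        assert counts.n_total == round(cts_spec.n_total / factor)
        assert sum(a for a, _ in counts.per_drug.values()) == counts.n_event
        assert sum(n for _, n in counts.per_drug.values()) == counts.n_total


def sim_spec(**overrides):
    base = dict(
        n_reports=50_000,
        drugs={"drugx": 0.01, "drugy": 0.02},
        background_p=0.01,
        injected={"drugx": 15.0},
        seed=42,
    )
    base.update(overrides)
    return SimulationSpec(**base)


def test_simulation_margins_match_materialized_reports():
    spec = sim_spec(n_reports=20_000)
    margins = simulate_margins(spec)
    counted = count_event_pairs(simulate_reports(spec), spec.event_pt)
    assert dict(counted.per_drug) == dict(margins.per_drug)
    assert counted.n_event == margins.n_event


def test_same_seed_reproduces_identical_reports():
    spec = sim_spec(n_reports=5_000)
    assert simulate_reports(spec).reports == simulate_reports(spec).reports
    other = simulate_reports(spec.model_copy(update={"seed": 43}))
    assert other.reports != simulate_reports(spec).reports


def test_null_simulation_rors_cluster_near_one():
    estimates = []
    for seed in range(10):
        spec = sim_spec(injected={}, n_reports=100_000, seed=seed)
        margins = simulate_margins(spec)
        for drug in ("drugx", "drugy"):
            estimates.append(ror(margins.table_for(drug))[0])
    assert np.mean(np.log(estimates)) == pytest.approx(0.0, abs=0.15)
    assert all(0.2 < e < 5.0 for e in estimates)


def test_injected_association_recovers_target_ror():
    spec = sim_spec(n_reports=300_000, injected={"drugx": 15.0})
    margins = simulate_margins(spec)
    est, lo, hi = ror(margins.table_for("drugx"))
    assert lo < 15.0 < hi


def test_event_probability_raises_odds_by_target_factor():
    spec = sim_spec()
    p0, p1 = spec.background_p, spec.event_probability("drugx")
    odds = lambda p: p / (1 - p)
    assert odds(p1) / odds(p0) == pytest.approx(15.0)
    assert spec.event_probability("drugy") == p0


@pytest.mark.parametrize(
    "overrides",
    [
        dict(drugs={"drugx": 1.2}),
        dict(drugs={"drugx": 0.6, "drugy": 0.6}),
        dict(injected={"ghost": 5.0}),
        dict(injected={"drugx": -1.0}),
    ],
)
def test_invalid_simulation_specs_rejected(overrides):
    with pytest.raises(ValueError):
        sim_spec(**overrides)
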
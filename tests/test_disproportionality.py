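"""ROR/PRR/chi-squared/BCPNN statistics: worked examples, algebraic
identities, and independent-oracle cross-checks."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import contingency as scipy_contingency

from pvsignals import BCPNNPriors, bcpnn_ic, build_table, chi_squared, compute_all, prr, ror
from pvsignals.contingency import ContingencyTable
from pvsignals.errors import UndefinedEstimateError

cells = st.integers(min_value=1, max_value=10_000)


def table(a, b, c, d):
    return ContingencyTable(drug="d", event_pt="e", a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# ROR
# ---------------------------------------------------------------------------


def test_ror_symmetric_table_is_exactly_one():
    est, lo, hi = ror(table(10, 10, 10, 10))
    assert est == pytest.approx(1.0)
    assert lo < 1.0 < hi


def test_ror_matches_printed_idursulfase_association():
    est, lo, hi = ror(build_table(54, 2064, 6837, 12929504))
    assert round(est, 1) == 51.2
    assert round(lo, 1) == 39.0


def test_ror_matches_printed_galsulfase_association():
    est, lo, hi = ror(build_table(20, 1435, 6837, 12929504))
    assert round(est, 1) == 26.8
    assert (round(lo, 1), round(hi, 1)) == (17.2, 41.7)


def test_ror_cross_checked_against_scipy_odds_ratio():
    t = build_table(54, 2064, 6837, 12929504)
    est, _, _ = ror(t)
    expected = scipy_contingency.odds_ratio(
        [[t.a, t.b], [t.c, t.d]], kind="sample"
    ).statistic
    assert est == pytest.approx(expected, rel=1e-12)


def test_zero_cell_requires_continuity_correction():
    with pytest.raises(UndefinedEstimateError):
        ror(table(0, 10, 5, 85))
    est, lo, hi = ror(table(0, 10, 5, 85), continuity=True)
    assert 0 < lo <= est <= hi
    # Haldane-Anscombe: all cells +0.5
    assert est == pytest.approx((0.5 / 5.5) / (10.5 / 85.5))


@settings(derandomize=True, max_examples=300)
@given(cells, cells, cells)
def test_ror_strictly_increasing_in_a(b, c, d):
    rors = [ror(table(a, b, c, d))[0] for a in (1, 2, 5, 17)]
    assert all(x < y for x, y in zip(rors, rors[1:]))


# ---------------------------------------------------------------------------
# PRR
# ---------------------------------------------------------------------------


def test_prr_symmetric_table_is_one():
    assert prr(table(10, 10, 10, 10)) == pytest.approx(1.0)


def test_prr_matches_exact_rational_arithmetic():
    t = build_table(54, 2064, 6837, 12929504)
    expected = (Fraction(54, 54 + 2010)) / Fraction(6783, 6783 + 12920657)
    assert prr(t) == pytest.approx(float(expected), rel=1e-12)


def test_prr_zero_cell_rejected_without_correction():
    with pytest.raises(UndefinedEstimateError):
        prr(table(0, 10, 5, 85))


@settings(derandomize=True, max_examples=300)
@given(cells, cells, cells, cells)
def test_prr_never_exceeds_ror_when_overreported(a, b, c, d):
    t = table(a, b, c, d)
    r = ror(t)[0]
    if r >= 1.0:
        assert prr(t) <= r + 1e-12


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------


def test_chi2_zero_on_exactly_independent_table():
    assert chi_squared(table(1, 9, 9, 81), yates=False) == pytest.approx(0.0)


def test_chi2_transpose_symmetry():
    t = table(7, 21, 13, 4)
    swapped = table(7, 13, 21, 4)
    assert chi_squared(t) == pytest.approx(chi_squared(swapped))


def test_chi2_matches_textbook_expected_count_formula():
    t = build_table(54, 2064, 6837, 12929504)
    n = t.n_total
    expected_stat = 0.0
    for obs, row, col in [
        (t.a, t.n_drug, t.n_event),
        (t.b, t.n_drug, n - t.n_event),
        (t.c, n - t.n_drug, t.n_event),
        (t.d, n - t.n_drug, n - t.n_event),
    ]:
        e = row * col / n
        expected_stat += (obs - e) ** 2 / e
    assert chi_squared(t, yates=False) == pytest.approx(expected_stat, rel=1e-9)
    assert chi_squared(t) >= 4.0


def test_chi2_yates_shrinks_statistic():
    t = table(30, 70, 20, 80)
    assert chi_squared(t, yates=True) < chi_squared(t, yates=False)


def test_chi2_degenerate_margin_returns_zero(caplog):
    with caplog.at_level("WARNING"):
        assert chi_squared(table(0, 0, 5, 85)) == 0.0
    assert "degenerate" in caplog.text


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------


def test_ic_no_information_limit_tends_to_zero():
    for n in (10_000, 1_000_000):
        ic, _, _ = bcpnn_ic(build_table(0, 0, 0, n))
        assert abs(ic) < 10 / n


def test_ic_near_zero_on_exactly_independent_large_table():
    ic, _, _ = bcpnn_ic(build_table(1, 1000, 1000, 1_000_000))
    assert abs(ic) < 0.1


def test_ic_asymptotic_limit_matches_observed_expected_ratio():
    # ratios fixed, all cells large: shrinkage must vanish
    t = build_table(10_000, 100_000, 100_000, 10_000_000)
    ic, _, _ = bcpnn_ic(t)
    limit = math.log2(t.a * t.n_total / (t.n_drug * t.n_event))
    assert ic == pytest.approx(limit, abs=0.01)


def test_ic025_positive_for_strong_association():
    ic, var, ic025 = bcpnn_ic(build_table(54, 2064, 6837, 12929504))
    assert ic025 > 0
    assert ic025 < ic
    assert var > 0


def test_ic025_shrinks_toward_zero_for_sparse_cells():
    # same observed/expected ratio, tiny counts: shrinkage pulls IC down
    big, _, _ = bcpnn_ic(build_table(1000, 10_000, 10_000, 1_000_000))
    small, _, _ = bcpnn_ic(build_table(1, 10, 10, 1000))
    assert small < big


def test_custom_priors_and_z_change_interval_only_sensibly():
    t = build_table(54, 2064, 6837, 12929504)
    _, _, at_196 = bcpnn_ic(t, BCPNNPriors(z=1.96))
    _, _, at_258 = bcpnn_ic(t, BCPNNPriors(z=2.58))
    assert at_258 < at_196


def test_compute_all_bundles_consistent_result():
    t = build_table(54, 2064, 6837, 12929504)
    r = compute_all(t)
    assert r.ror_ci_low <= r.ror <= r.ror_ci_high
    assert r.ic025 <= r.ic_expected
    assert r.corrections_applied == frozenset()
    assert r.prr == pytest.approx(prr(t))
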
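"""Frequentist and Bayesian disproportionality statistics for 2x2 tables.

Given the report-level table (a, b, c, d) for one drug--event pair:

* reporting odds ratio  ROR = (a/c)/(b/d), with a Woolf (log-normal)
  95% confidence interval  exp(ln ROR +/- z*sqrt(1/a + 1/b + 1/c + 1/d));
* proportional reporting ratio  PRR = (a/(a+b)) / (c/(c+d));
* Pearson chi-squared with 1 df (Yates continuity correction by default);
* the BCPNN information component IC = log2 P(drug, event) /
  (P(drug) P(event)) under the closed-form posterior-moment approximation
  with Dirichlet-style pseudo-counts, and its lower interval bound IC025.

All statistics are computed in full precision; rounding to the customary
one decimal place is presentation-only and happens in the report writers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

from pydantic import BaseModel, Field
from scipy.stats import chi2_contingency

from .contingency import ContingencyTable
from .errors import UndefinedEstimateError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BCPNNPriors",
    "DisproportionalityResult",
    "ror",
    "prr",
    "chi_squared",
    "bcpnn_ic",
    "compute_all",
]

_LN2 = math.log(2.0)


class BCPNNPriors(BaseModel):
    """Pseudo-counts and interval multiplier for the information component.

    The defaults (alpha1 = beta1 = gamma11 = 1, alpha = beta = 2, z = 1.96)
    are the customary symmetric choice: a priori the drug and the event each
    occur in half of all reports and are independent, so IC shrinks toward 0
    for sparse cells.
    """

    alpha1: float = Field(default=1.0, gt=0)
    beta1: float = Field(default=1.0, gt=0)
    alpha: float = Field(default=2.0, gt=0)
    beta: float = Field(default=2.0, gt=0)
    gamma11: float = Field(default=1.0, gt=0)
    z: float = Field(default=1.96, gt=0)


@dataclass(frozen=True)
class DisproportionalityResult:
    table: ContingencyTable
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic_expected: float
    ic_variance: float
    ic025: float
    corrections_applied: frozenset[str] = frozenset()


def _cells(t: ContingencyTable, continuity: bool) -> tuple[float, float, float, float]:
    if min(t.a, t.b, t.c, t.d) == 0:
        if not continuity:
            raise UndefinedEstimateError(
                f"zero cell in table for {t.drug or '<drug>'!r}; "
                "enable the Haldane-Anscombe continuity correction"
            )
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5
    return float(t.a), float(t.b), float(t.c), float(t.d)


def ror(
    t: ContingencyTable, z: float = 1.96, continuity: bool = False
) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf ``z``-interval.

    Returns ``(ror, ci_low, ci_high)``.  With ``continuity`` every cell
    gets +0.5 (Haldane-Anscombe) before estimation; otherwise a zero cell
    raises :class:`UndefinedEstimateError`.
    """
    a, b, c, d = _cells(t, continuity)
    estimate = (a / c) / (b / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = z * se
    log_est = math.log(estimate)
    return estimate, math.exp(log_est - half), math.exp(log_est + half)


def prr(t: ContingencyTable, continuity: bool = False) -> float:
    """Proportional reporting ratio (a/(a+b)) / (c/(c+d))."""
    a, b, c, d = _cells(t, continuity)
    return (a / (a + b)) / (c / (c + d))


def chi_squared(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-squared (1 df) on the 2x2 table.

    ``yates`` applies the continuity correction (|O-E| reduced by 0.5).
    A degenerate margin (an all-zero row or column) yields 0 with a warning
    rather than an error -- such tables carry no association evidence.
    """
    if t.n_total <= 0:
        raise ValidationError("chi_squared requires n_total > 0")
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        logger.warning("degenerate margin in table for %r; chi2 set to 0", t.drug)
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=yates)
    return float(res.statistic)


def bcpnn_ic(
    t: ContingencyTable, priors: BCPNNPriors | None = None
) -> tuple[float, float, float]:
    """Information component: posterior expectation, variance, and IC025.

    Closed-form moments of IC = log2 p11/(p1. * p.1) under Beta/Dirichlet
    priors with pseudo-counts from ``priors``.  The joint pseudo-count
    gamma is rescaled so the prior is centred on independence:
    gamma = gamma11 * (N+alpha)(N+beta) / ((n1+alpha1)(n2+beta1)).
    IC025 = E[IC] - z*sqrt(V[IC]) (normal approximation).
    """
    if priors is None:
        priors = BCPNNPriors()
    if t.n_total <= 0:
        raise ValidationError("bcpnn_ic requires n_total > 0")
    n = float(t.n_total)
    n1 = float(t.n_drug)
    n2 = float(t.n_event)
    a = float(t.a)
    p = priors
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((n1 + p.alpha1) * (n2 + p.beta1))
    ic_expected = math.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
        / ((n + gamma) * (n1 + p.alpha1) * (n2 + p.beta1))
    )
    ic_variance = (1.0 / _LN2) ** 2 * (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - n1 + p.alpha - p.alpha1) / ((n1 + p.alpha1) * (1 + n + p.alpha))
        + (n - n2 + p.beta - p.beta1) / ((n2 + p.beta1) * (1 + n + p.beta))
    )
    ic025 = ic_expected - p.z * math.sqrt(ic_variance)
    return ic_expected, ic_variance, ic025


def compute_all(
    t: ContingencyTable,
    z: float = 1.96,
    priors: BCPNNPriors | None = None,
    continuity: bool = False,
    yates: bool = True,
) -> DisproportionalityResult:
    """All four statistics for one table as a :class:`DisproportionalityResult`."""
    estimate, lo, hi = ror(t, z=z, continuity=continuity)
    corrections = frozenset({"continuity"}) if continuity and min(t.a, t.b, t.c, t.d) == 0 else frozenset()
    ic_e, ic_v, ic_low = bcpnn_ic(t, priors)
    return DisproportionalityResult(
        table=t,
        ror=estimate,
        ror_ci_low=lo,
        ror_ci_high=hi,
        prr=prr(t, continuity=continuity),
        chi2=chi_squared(t, yates=yates),
        ic_expected=ic_e,
        ic_variance=ic_v,
        ic025=ic_low,
        corrections_applied=corrections,
    )
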
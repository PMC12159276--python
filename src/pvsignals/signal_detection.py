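"""Layered signal-detection rules over disproportionality results.

Three screens are combined conjunctively for each drug--event pair:

1. the Evans et al. criteria — at least ``min_cases_evans`` reports of the
   pair, PRR >= ``min_prr`` and chi-squared >= ``min_chi2``;
2. Bayesian validation — the lower 95% bound of the information component
   strictly positive (IC025 > 0);
3. custom robustness thresholds — at least ``min_cases_custom``
   primary-suspect reports of the pair and ROR >= ``min_ror``, which screen
   out statistically significant but numerically fragile associations.

``detect_signals`` evaluates every primary-suspect drug in a report set and
returns a ranked table: signals first (ROR descending), then non-signals
(ROR descending), ties broken by drug name.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from pydantic import BaseModel, Field

from .contingency import EventCounts, count_event_pairs
from .disproportionality import BCPNNPriors, DisproportionalityResult, compute_all
from .report_store import ReportSet

logger = logging.getLogger(__name__)

__all__ = ["SignalCriteria", "SignalDecision", "evaluate_pair",
           "detect_signals", "detect_signals_from_counts", "write_signal_table"]


class SignalCriteria(BaseModel):
    min_cases_evans: int = Field(default=3, ge=0)
    min_prr: float = Field(default=2.0, ge=0)
    min_chi2: float = Field(default=4.0, ge=0)
    require_ic025_positive: bool = True
    min_cases_custom: int = Field(default=10, ge=0)
    min_ror: float = Field(default=10.0, ge=0)


@dataclass(frozen=True)
class SignalDecision:
    drug: str
    result: DisproportionalityResult
    evans_pass: bool
    bcpnn_pass: bool
    custom_pass: bool

    @property
    def is_signal(self) -> bool:
        return self.evans_pass and self.bcpnn_pass and self.custom_pass


def evaluate_pair(r: DisproportionalityResult, c: SignalCriteria) -> SignalDecision:
    """Apply all screens to one pair; case counts use the raw cell a."""
    a = r.table.a
    evans = a >= c.min_cases_evans and r.prr >= c.min_prr and r.chi2 >= c.min_chi2
    bcpnn = (r.ic025 > 0) if c.require_ic025_positive else True
    custom = a >= c.min_cases_custom and r.ror >= c.min_ror
    return SignalDecision(
        drug=r.table.drug, result=r, evans_pass=evans, bcpnn_pass=bcpnn, custom_pass=custom
    )


def detect_signals_from_counts(
    counts: EventCounts,
    criteria: SignalCriteria | None = None,
    priors: BCPNNPriors | None = None,
) -> list[SignalDecision]:
    """Evaluate every drug in a margin set (one decision per drug with
    ``n_drug >= 1``).

    Tables with a zero cell get the Haldane-Anscombe correction so their
    audit statistics exist; the raw case count still drives the case-floor
    thresholds, so corrected pairs cannot sneak past the floors.
    """
    if criteria is None:
        criteria = SignalCriteria()
    decisions: list[SignalDecision] = []
    for t in counts.tables():
        continuity = min(t.a, t.b, t.c, t.d) == 0
        result = compute_all(t, priors=priors, continuity=continuity)
        decisions.append(evaluate_pair(result, criteria))
    decisions.sort(key=lambda s: (not s.is_signal, -s.result.ror, s.drug))
    return decisions


def detect_signals(
    rs: ReportSet,
    event_pt: str,
    criteria: SignalCriteria | None = None,
    priors: BCPNNPriors | None = None,
) -> list[SignalDecision]:
    """Count pairs in ``rs`` and rank all drug decisions for one event."""
    counts = count_event_pairs(rs, event_pt)
    if counts.n_event == 0:
        logger.warning("event %r absent from report set; no decisions", event_pt)
        return []
    return detect_signals_from_counts(counts, criteria, priors)


def write_signal_table(decisions: list[SignalDecision], path: str | Path) -> None:
    """Ranked TSV signal table; ratio statistics rounded for presentation."""
    cols = ["drug", "a", "n_drug", "pct_event", "ror", "ci_low", "ci_high",
            "prr", "chi2", "ic_expected", "ic025",
            "evans_pass", "bcpnn_pass", "custom_pass", "is_signal"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for s in decisions:
            t = s.result.table
            pct = 100.0 * t.a / t.n_drug if t.n_drug else 0.0
            w.writerow([
                s.drug, t.a, t.n_drug, f"{pct:.1f}",
                f"{s.result.ror:.1f}", f"{s.result.ror_ci_low:.1f}",
                f"{s.result.ror_ci_high:.1f}", f"{s.result.prr:.2f}",
                f"{s.result.chi2:.2f}", f"{s.result.ic_expected:.3f}",
                f"{s.result.ic025:.3f}",
                s.evans_pass, s.bcpnn_pass, s.custom_pass, s.is_signal,
            ])
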
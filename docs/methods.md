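# Methods

## Data model and counting conventions

The unit of analysis is the *report* (one spontaneous case report). A
report carries one or more drugs with role codes (primary suspect,
secondary suspect, concomitant, interacting) and one or more reaction
preferred terms. All counting is at report level: a drug–event pair
contributes at most one count per report however often it is listed, and
a report with several distinct primary-suspect drugs contributes to each
of their tables.

For a drug D and event term E the 2×2 table counts

|            | event E | not E |
|------------|---------|-------|
| D primary suspect | a | b |
| other drugs       | c | d |

with margins `n_drug = a+b` (reports naming D as primary suspect),
`n_event = a+c` (reports carrying E under any drug and role), and
`n_total = a+b+c+d` equal to the database size. Counting the comparator
cells per report (rather than per drug mention) keeps the four cells
summing to the report total, which is the denominator convention behind
the packaged fixture's totals. Drug names and preferred terms are
normalized by trimming, case-folding and collapsing internal whitespace;
no synonym mapping or term-hierarchy expansion is applied, so distinct
names for the same substance (e.g. "alendronate" and "alendronic acid")
remain distinct drugs. Event matching is exact string equality on the
normalized preferred term.

## Statistics

**ROR.** `ROR = (a/c)/(b/d)` with the Woolf (log-normal) interval
`exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`, `z = 1.96` by default. The
interval is asymptotic; its finite-sample coverage at moderate margins
is checked by simulation in the test suite (93–97% at a true odds ratio
of 1).

**PRR.** `PRR = (a/(a+b))/(c/(c+d))`. Whenever `ROR ≥ 1`, `PRR ≤ ROR`
(algebraic identity on positive cells); the suite asserts this over
randomized tables.

**Zero cells.** ROR and PRR are undefined on tables with a zero cell and
raise by default. The optional Haldane–Anscombe correction (+0.5 to all
four cells) can be enabled per call; the signal pipeline enables it
automatically for zero-cell tables so that every drug receives auditable
statistics, and records the correction in the result. Case-count
thresholds always use the raw cell `a`, so corrected statistics cannot
lift a pair over a case floor.

**χ².** Pearson's statistic with 1 df, delegated to
`scipy.stats.chi2_contingency`, with the Yates continuity correction on
by default (the convention under which the χ² ≥ 4 screen was proposed);
a flag disables it. A degenerate margin (an all-zero row or column)
yields 0 with a warning rather than an error, since such tables carry no
association evidence.

**BCPNN information component.** `IC = log₂ p₁₁/(p₁·p·₁)` with Beta/
Dirichlet pseudo-counts; the closed-form posterior moments are

    γ        = γ₁₁ (N+α)(N+β) / ((n₁+α₁)(n₂+β₁))
    E[IC]    = log₂ [ (a+γ₁₁)(N+α)(N+β) / ((N+γ)(n₁+α₁)(n₂+β₁)) ]
    V[IC]    = (1/ln2)² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                        + (N−n₁+α−α₁)/((n₁+α₁)(1+N+α))
                        + (N−n₂+β−β₁)/((n₂+β₁)(1+N+β)) ]
    IC025    = E[IC] − z·√V[IC]

with `N = n_total`, `n₁ = n_drug`, `n₂ = n_event`. Defaults
`α₁ = β₁ = γ₁₁ = 1`, `α = β = 2`, `z = 1.96`: the symmetric prior centred
on independence, under which IC shrinks toward 0 for sparse cells and
converges to `log₂(aN/(n₁n₂))` as all cells grow (verified to 0.01 bits
at N = 10⁷). The source methodology does not pin these constants, so
they are exposed in `BCPNNPriors` for sensitivity analysis; `z = 1.96`
for IC025 is likewise a documented assumption (some systems use 2.0).
The normal approximation to the IC posterior is used throughout; no
posterior sampling.

## Signal criteria

A pair is a signal iff all three screens pass:

1. **Evans**: `a ≥ 3`, `PRR ≥ 2`, `χ² ≥ 4`;
2. **Bayesian validation**: `IC025 > 0` (strict; can be waived);
3. **robustness floors**: `a ≥ 10` and `ROR ≥ 10` (both inclusive),
   screening out significant but numerically fragile pairs.

The conjunction is order-independent. No multiple-testing adjustment is
applied — by design the procedure mirrors single-pair screening practice —
but every run records the number of pairs tested in its manifest so the
reader can judge the implied burden. Output is ranked signals first
(ROR descending), then non-signals (ROR descending), ties broken by drug
name; drugs with zero event reports stay in the table for audit but can
never be flagged.

## Descriptive summaries

Sex percentages are computed over the event's reports and rounded to one
decimal at presentation; age mean and SD (sample SD, n−1) use only
reports with a stated age — whether published summaries do likewise is
usually unstated, so this choice is documented rather than assumed
universal. Ages reported in months or days are converted to years at
parse time. Yearly counts cover observed years only; no smoothing.

## Synthetic data

**Exact reconstruction.** A `MarginSpec` lists the event term, the
database totals `(n_total, n_event)` and per-drug margins `(a, n_drug)`;
a filler drug absorbs the remaining reports and a filler reaction the
remaining non-event reports, so every synthetic report carries exactly
one primary-suspect drug and one reaction. Feasibility
(`a ≤ n_drug`, `Σ n_drug ≤ n_total`, `Σ a ≤ n_event`, filler
non-negativity) is validated on construction with the violated
inequality named. Demographics, when specified, are assigned to the
event reports so sex and country counts match exactly; ages are seeded
normal draws clipped to [0, 130] (matching the requested mean/SD to
sampling error), years seeded uniform over the requested range.
Demographics of non-event reports are unconstrained by any published
margin and are left blank. Reconstruction is deterministic given the
seed.

Down-scaling divides every count by a factor with largest-remainder
rounding applied jointly, so the scaled per-drug counts still sum to the
scaled totals; note that drugs whose scaled quota falls below 0.5 can
round to zero event reports. Full-scale sets (~1.3×10⁷ reports) are
written by a streaming generator rather than materialized; in-memory
reconstruction with `include_filler=False` yields only the event reports
(the filler reports carry no information beyond their count), with the
true `n_total` passed explicitly to the summarizer.

**Stochastic simulation.** A `SimulationSpec` gives a drug catalogue
with marginal probabilities, a background event probability `p₀`, and
injected `(drug, target_ror)` pairs. Injected drugs receive event odds
`target_ror × p₀/(1−p₀)`, so the expected odds ratio against the
all-other-drugs comparator equals the target exactly (other drugs all
report at `p₀`). Drug assignment is drawn as one multinomial over the
catalogue and event counts as one binomial per drug — distributionally
identical to per-report draws — and reports are then materialized
deterministically from those counts, so the fast margin-level path
(`simulate_margins`) and the materialized path (`simulate_reports`)
agree cell-for-cell on the same seed. The simulator emulates the
statistical skeleton of a reporting database, not its texture: no
polypharmacy correlation, reporting lag, duplicate case versions, or
realistic drug vocabularies. Passing recovery tests therefore shows the
estimators are correct under the stated sampling model, not that real
extraction pipelines are artifact-free.

The packaged fixture (`pvsignals/data/cts_faers_margins.yaml`) is a
synthetic margin specification encoding the carpal-tunnel-syndrome
reference margins: totals 12,929,504 / 6,837, ten drug rows, and the
event-report demographics (4,753 F / 1,717 M / 367 unknown, age
57.0 ± 14.9, 4,699 US reports, years 2004–2024).

## Problem sizes used in the checks

The parameter-recovery study injects a target odds ratio of 20 into
500,000-report databases over 50 seeds (drug share 1%, background event
probability 0.5%, giving expected pair counts well above the case
floors) and runs at margin level. Interval-coverage checks use 2,000
simulated null tables with 500/9,500 drug/comparator reports at 5% event
probability. Oracle-equivalence checks for pair counting run a
brute-force double loop on report sets of up to 200 reports.
Reconstruction checks materialize the fixture at 1/1000 scale plus the
full event-report subset; the acceptance script verifies a 1/1000-scale
materialization cell-by-cell before computing full-scale estimates from
the margins.

## Known limitations

* One event term per run; scanning all preferred terms is the caller's
  loop.
* No stratified (age/sex/year, Mantel–Haenszel) analysis, no MGPS/EBGM,
  no MCMC posterior for IC.
* String-level event matching; no MedDRA hierarchy traversal or synonym
  mapping.
* The reader assumes pre-deduplicated input (one row set per case); real
  quarterly-extract quirks (case versioning, legacy identifiers) are out
  of scope.
* Two reference point estimates (laronidase, alendronic acid) recompute
  one last-decimal step below their published values under report-level
  counting (20.8 vs 20.9, 17.0 vs 17.1); the published source's counting
  unit for those cells cannot be established from its printed margins,
  and report-level counting is this package's contract.
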
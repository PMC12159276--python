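# Margin fixture: drugs most strongly associated with carpal tunnel
# syndrome in a FAERS-scale spontaneous-report database (reports from
# October 2003 to September 2024).  Per-drug values are (a, n_drug) =
# (primary-suspect reports with the event, primary-suspect reports total).
event_pt: carpal tunnel syndrome
n_total: 12929504
n_event: 6837
drugs:
  - {drug: idursulfase, a: 54, n_drug: 2064}
  - {drug: galsulfase, a: 20, n_drug: 1435}
  - {drug: laronidase, a: 28, n_drug: 2577}
  - {drug: tesamorelin, a: 23, n_drug: 2130}
  - {drug: anastrozole, a: 109, n_drug: 10273}
  - {drug: alendronic acid, a: 151, n_drug: 17251}
  - {drug: gamma-hydroxybutyric acid, a: 14, n_drug: 1640}
  - {drug: rofecoxib, a: 268, n_drug: 32890}
  - {drug: alendronate, a: 157, n_drug: 23592}
  - {drug: tafamidis, a: 55, n_drug: 8770}
filler_drug_name: other suspect drug
filler_reaction: drug ineffective
demographics:
  n_female: 4753
  n_male: 1717
  n_unknown: 367
  age_mean: 57.0
  age_sd: 14.9
  countries:
    US: 4699
  year_start: 2004
  year_end: 2024
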
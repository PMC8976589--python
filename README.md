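# neolos

Composite inflammation/organ-failure scoring and two-timepoint analysis
for preterm neonates with suspected late-onset sepsis (LOS).

Diagnosing LOS in very preterm infants (< 32 weeks gestation) is hard:
presentations are nonspecific, cultures take days, and empirical
antibiotics are often started on suspicion alone. `neolos` implements a
simple bedside severity score built from five routinely available
parameters, and the statistical pipeline needed to ask whether that
score — measured at the timing of suspicion (t1) and again 24–48 hours
later (t2) — predicts a positive culture study (blood, urine or CSF).
It is aimed at neonatologists and biostatisticians who want to evaluate
or re-calibrate this kind of score on their own cohort, or to prototype
study designs on synthetic data.

## The score

| component | rule | points |
|---|---|---|
| WBC (×10⁹/L) | outside the closed band [4, 20] | 0–1 |
| Platelets (×10⁹/L) | ≥150 → 0; 100–150 → 1; 50–100 → 2; <50 → 3 | 0–3 |
| CRP (mg/L) | <10 → 0; 10–30 → 1; 30–50 → 2; ≥50 → 3 | 0–3 |
| Ventilation | none → 0; non-invasive → 1; invasive → 2 | 0–2 |
| S/F = SpO₂(%)/FiO₂(fraction) | ≥300 → 0; 200–300 → 1; 150–200 → 2; 100–150 → 3; <100 → 4 | 0–4 |

The analytical sub-score is WBC + PLT + CRP (0–7), the respiratory
sub-score ventilation + S/F (0–6), and the total 0–13. Every cut-off is
configurable through a YAML rubric (see
`src/neolos/data/default_rubric.yaml`); all bins are lower-bound
inclusive, so a value sitting exactly on a cut-off takes the bin that
starts there.

The analysis battery is the one this kind of small two-group cohort
calls for: Mann–Whitney U (tie-corrected asymptotic, exact for small
untied samples) with median [IQR] summaries; uncorrected Pearson χ² or
two-sided Fisher exact tests on the paired-change indicators (score
rose, platelets fell, CRP rose, interval intubation), chosen by the
classic expected-cell < 5 rule; and for every variable significant at
p < 0.05, a rank-based ROC AUC with the Hanley–McNeil standard error,
Wald 95% CI, and a null-variance z test of AUC = 0.5. Platelets are
analysed with the `lower_predicts_positive` orientation
(thrombocytopenia is the sepsis signal). P-values are deliberately
unadjusted — the report says so in every row.

## Worked example

Generate a synthetic cohort with the shipped calibration (15
culture-negative / 18 culture-positive episodes, group-wise marker
medians and IQRs, ventilation escalation and missingness matching a
published preterm LOS cohort), then analyse it:

```sh
neolos simulate --seed 7 --output demo.csv
neolos analyze --input demo.csv --output report.tsv
```

`report.tsv` (excerpt; `report.tsv.json` carries the same numbers
machine-readably):

```text
variable     timing  negative_summary          positive_summary          n_neg  n_pos  test                     p_value  adjustment  auc    auc_ci     auc_p   orientation
plt          t2      411.46 [305.788-491.785]  118.958 [95.2195-169.121] 15     18     mann_whitney_asymptotic  0.0005   unadjusted  0.859  0.73-0.99  0.0005  lower_predicts_positive
crp          t2      2.02189 [0.343318-4.71195] 41.6764 [20.4439-84.8098] 15    18     mann_whitney_asymptotic  0.0000   unadjusted  0.967  0.90-1.00  0.0000  higher_predicts_positive
total_score  t2      1 [0-2]                   5 [3.5-6.75]              15     14     mann_whitney_asymptotic  0.0001   unadjusted  0.929  0.83-1.00  0.0001  higher_predicts_positive
```

Read: at the second timing the culture-positive group has a median
total score of 5 against 1 in the negative group; the score
discriminates with AUC 0.93 (a randomly chosen positive episode
out-scores a randomly chosen negative one 93% of the time, ties ½).
Platelets discriminate in the *low* direction, which is why their
orientation is printed.

`neolos reproduce-table` recomputes the four published paired-change
contingency tests from their built-in counts:

```text
indicator                               table            test              computed_p  printed_p
Higher score in the second measure      [[3,11],[10,5]]  chi2_uncorrected  0.014       0.014
Lower PLT count in the second measure   [[9,6],[13,3]]   fisher_two_sided  0.252       0.252
Higher CRP value in the second measure  [[4,10],[12,4]]  chi2_uncorrected  0.011       0.011
Intubation between both measures        [[0,15],[7,10]]  fisher_two_sided  0.008       0.008
```

`neolos score --input demo.csv` prints per-episode component scores,
sub-scores and totals at both timings under a chosen missing-value
policy.

## Limitations

The synthetic generator reproduces published *marginal* summaries, one
within-subject correlation knob and ventilation transition rates — not
the raw cohort's joint distribution — so individual-level p-values and
AUCs from the original study are not reproducible from it (see
`docs/methods.md`). The score is a research tool, not clinical decision
support.
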
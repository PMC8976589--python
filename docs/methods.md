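# Methods

## The score and its boundary conventions

The composite severity score sums five component scores: WBC (0–1),
platelets (0–3), CRP (0–3), ventilation support (0–2) and SpO₂/FiO₂
ratio (0–4), giving a 0–13 total; WBC + PLT + CRP form the analytical
sub-score and ventilation + S/F the respiratory sub-score. The clinical
cut-offs follow neonatal sepsis consensus bands for WBC and platelets
and a unit-level empirical severity classification for CRP, which is
exactly why the whole rubric is a configuration object
(`neolos.score_core.Rubric`, shipped defaults in
`src/neolos/data/default_rubric.yaml`) rather than hard-coded
constants.

Published band descriptions of this kind overlap at their edges
("100–150" vs "above 150"), so one explicit convention is fixed here:
every graded component is binned **lower-bound inclusive** — a value
equal to a cut-off takes the bin that starts at that cut-off. Hence
PLT 150 → 0, CRP 10 → 1, CRP 50 → 3, S/F 300 → 0, S/F 150 → 2. The WBC
normal band is closed on both sides, [4, 20]; in the bin table this is
expressed by starting the upper abnormal bin at the smallest float
above 20. The convention is declared, not inferred from the source
material, and lives in a single bin table so a different convention is
a config edit away.

**Units.** The S/F ratio is SpO₂ in percent divided by FiO₂ as a
fraction: a well-saturated neonate on room air sits near 98/0.21 ≈ 467,
and the 100–300 bin edges then correspond to clinically meaningful
hypoxemia. A directly recorded `sf_ratio` takes precedence over
recomputation from SpO₂/FiO₂; a disagreement above one unit warns but
does not fail, since charted ratios and charted saturations are often
asynchronous.

**Missing components.** Small-cohort registries rarely have every
parameter at every timing. Three policies are provided:
`propagate_missing` (default: any missing component makes the affected
sub-score and total missing), `zero_impute` (missing contributes 0,
with `n_missing_components` recorded so downstream consumers can see
the imputation), and `strict` (error naming the component). The default
is conservative: a total computed from four components is not the same
quantity as one computed from five.

## Statistical battery

* **Mann–Whitney U** (two-sided): mid-rank U with the tie-corrected
  normal approximation and no continuity correction as the default;
  exact enumeration is used when requested and the pooled sample is
  tie-free with ≤ 25 observations. A fully tied sample returns p = 1.
  Backed by `scipy.stats.mannwhitneyu`; verified in the tests against a
  complete-enumeration oracle.
* **2×2 tests**: uncorrected Pearson χ² (df = 1, Yates available by
  flag) and the two-sided Fisher exact test under the probability-mass
  convention (sum of all same-margin tables whose hypergeometric
  probability is at most the observed table's). These two conventions
  are the ones that reproduce all four published paired-change
  p-values from their counts (0.014, 0.011 by uncorrected χ²; 0.008,
  0.252 by Fisher). Notably the "lower platelet count" row carries a χ²
  footnote in the source table but its printed p = 0.252 is only
  reproduced by Fisher — the pipeline therefore selects the test by the
  classic rule (Fisher whenever any expected cell < 5) and always
  reports the test actually used.
* **ROC/AUC**: AUC by the rank identity AUC = U/(n₊·n₋) with ties
  counted ½; standard error by the Hanley–McNeil approximation
  (Q₁ = A/(2−A), Q₂ = 2A²/(1+A)), consistent with legacy statistical
  packages; Wald 95% CI clipped to [0, 1]; p-value from a z test of
  AUC = 0.5 using the null-variance form (N+1)/(12·n₊·n₋). A DeLong-style
  variance was considered and not adopted: without the original raw
  data neither convention can be checked against the published CIs, and
  Hanley–McNeil matches the software family such studies typically use.
* **Summaries**: medians with 25th–75th percentile IQRs; percentile
  rule `interpolate` (linear interpolation) by default, with
  `package_compat` (the weighted-average (n+1)p convention) as a flag
  because printed IQRs depend on this choice.
* **Multiplicity**: no adjustment, matching the design being emulated;
  every report row carries an explicit "unadjusted" label.
* **Promotion to ROC**: any compared variable with p < 0.05 (threshold
  configurable) is promoted; platelets are analysed under
  `lower_predicts_positive` since thrombocytopenia, not thrombocytosis,
  is the sepsis signal, and the orientation is always printed.

## Synthetic cohort generator

The generator emulates a two-timepoint preterm LOS cohort at its
published *marginal* structure. Defaults are the study conditions: 15
culture-negative and 18 culture-positive episodes; per-group,
per-timing median/IQR targets for WBC, platelets and CRP taken from the
published group summaries (e.g. platelets 420 [301–549] vs 230
[170–325] ×10⁹/L at suspicion); an escalation-to-invasive-ventilation
probability of 7/17 between timings for positives and 0 for negatives;
organism labels that are *Staphylococcus epidermidis* with probability
2/3 for positives (cosmetic only); and a 3% per-field missingness rate,
chosen so the expected per-indicator denominators land in the 14–17
range the published percentages imply.

Design choices the published summaries do not determine, fixed here
once:

* **Families.** Platelets and CRP are two-piece log-normal (right-skewed
  positive quantities); WBC is two-piece normal clipped at zero.
  Clipping rather than resampling is deliberate: it leaves the three
  target quantiles untouched. Each half of a two-piece distribution
  gets its own scale solved in closed form from the median and the
  corresponding quartile (s = ln(q₃/m)/z₇₅ on the log scale, or
  (q₃−m)/z₇₅ on the data scale), so the theoretical median and
  quartiles equal the targets exactly, including asymmetric IQRs.
* **Within-subject correlation.** The two timings share a latent
  standard normal, z₂ = ρ·z₁ + √(1−ρ²)·ε with ρ = 0.5 per marker — a
  rank-preserving coupling. ρ is a config knob, not a claim: the real
  within-subject correlation is unknowable from group summaries, and
  the paired-change indicators depend on it.
* **S/F.** Never drawn directly: SpO₂ (two-piece normal, median 95
  [93, 97.5], clipped to [80, 100]) and FiO₂ (0.21 for unventilated
  episodes; 0.21 plus a log-normal supplement otherwise, with a higher
  supplement target for positives at the second timing) are simulated
  and the observation derives the ratio.
* **Descriptive fields.** Gestational age and birthweight are generated
  from the published medians for realism but are never consumed by the
  analysis.
* **Missingness** is masked independently per field (MCAR). The real
  missingness mechanism is unknowable from the source material; the
  rate is a config knob.

What passing tests on synthetic cohorts therefore show: the pipeline's
arithmetic, its handling of missingness and ties, type-I error control,
and recovery of effect *direction* under the calibrated group
separation. What they cannot show: the original study's exact
Mann–Whitney p-values and AUCs (0.798 for the second-timing total
score, 0.767/0.892 for platelets, 0.807 for CRP, 0.800 for the
analytical sub-score), which depend on the unavailable raw joint
distribution. Those quantities are covered instead by oracle
equivalences (Fisher vs complete enumeration, AUC vs pair counting,
exact Mann–Whitney vs labeling enumeration) and by the
direction-recovery property: across replicate calibrated cohorts the
second-timing score AUC exceeds 0.5 in ≥ 99% of replicates.

## Verification problem sizes and numerical choices

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: exhaustive Fisher equivalence over all 135,750 tables with
total ≤ 40; 1,000 random datasets for the AUC/pair-counting identity;
type-I error on label-permuted cohorts with the acceptance band fixed
at the 2,000-replicate Monte-Carlo width (the suite runs 8,000
replicates so estimator noise is small relative to that band; the
acceptance script reports rates at 2,000). Calibration recovery is
judged on the median of per-cohort group medians across 30 replicate
cohorts at 100× scale: a single cohort's sample median of a
heavy-tailed marker (CRP, log-scale σ ≈ 2.5 below the median) has ~6%
relative sampling noise even at n = 1,500, so the replicate median is
the right estimator for a 5% calibration check.

In the type-I study the exact Mann–Whitney test is applied to a random
8 + 8 subsample of the permuted groups; subsampling "the first eight"
of each group would break exchangeability (the groups have unequal
sizes, so the sparser label reaches deeper into the block-ordered
episode list) and was observed to inflate the rejection rate — the
random subsample restores validity.

Tie handling: Fisher's probability-mass comparison uses a 1e−7 relative
tolerance when comparing table probabilities; change indicators treat
|Δ| ≤ tolerance (default 0) as "no change"; rank AUC counts ties ½.

## Known limitations

* The generator makes no attempt at the real joint distribution beyond
  marginals, one correlation knob and ventilation transitions; no
  informative missingness.
* The second timing is a 24–48 h *window* collapsed to one observation;
  window enforcement is a validation concern left to the data owner.
* Only one episode per neonate is modelled (first-episode designs);
  there are no repeated-measures structures, no mortality or
  length-of-stay endpoints, and no comparison against other published
  neonatal organ-failure scores.
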
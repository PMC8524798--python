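# Methods

## The screening model

A medication *snapshot* is the set of ATC codes a patient takes at one
assessment time; five assessment times are modelled (admission `t0`,
discharge `t1`, and telephone follow-up at 2, 6 and 12 months).  A snapshot
is already concurrent use, so no within-timepoint temporal overlap logic is
needed or attempted.

Each of the 66 consensus rules is expressed entirely through ATC-prefix
groups with optional exclusion prefixes; membership of a code is "some
include prefix is an ancestor, no exclude prefix is".  Two consequences are
worth stating explicitly:

- **Route restrictions** ("oral NSAID", "inhaled beta2 agonist", "systemic
  corticosteroid") are expressed through ATC class choice alone (M01A vs
  M02A topicals; R03A inhaled vs R03C systemic; H02AB), because the input
  schema carries no route field.
- **Fixed-dose combination products** are matched only by their own
  prefixes; they are not decomposed into components, which would need an
  external composition database.  A combination code can therefore satisfy
  only the group(s) its own prefix belongs to — a documented
  false-negative source.

A pairwise rule needs two *distinct* codes, one per group: an interaction
needs two agents, and one physical code never pairs with itself even when
the two groups overlap.  A cardinality rule needs `min_count` distinct
matching codes.  Multiplicity is counted at rule level: however many drug
combinations satisfy one rule in one snapshot, it is one hit, with all
matching codes kept as the triggering set.  Distinct full ATC codes of the
same substance count as distinct drugs; the alternative (substance-level
deduplication) would need a code-to-substance map and is left to
sensitivity analyses.

Invalid codes in input are skipped with a logged warning rather than
failing the cohort — telephone-interview medication data are messy, and an
audit trail beats a crash.

The cohort screening path compiles the rule set into a boolean
codes-by-groups membership matrix and gets per-snapshot group counts by
matrix multiplication; a pairwise rule fires iff both group counts are
positive and the union column counts at least two distinct codes.  Tests
assert its exact agreement with the straightforward per-snapshot evaluator
and with exhaustive pair/subset enumeration.

## Longitudinal accounting

Eligibility requires snapshots at both `t0` and `t1`.  After discharge, the
censoring rule is: the first follow-up assessment with no medication data
ends the patient's contribution, and any later snapshots are discarded
(data at `t` with no data at `t−1` never count).  Deaths, withdrawals and
missing interviews are deliberately pooled in this one mechanism; no
imputation is performed.

Point-prevalence at a timepoint divides patients with at least one
qualifying hit by all non-censored patients (within the stratum for
arm/site strata).  Rules with mechanism "both" count in both the
pharmacokinetic and the pharmacodynamic stratum, so mechanism strata do
not sum to the overall count.  The "most common" rules are those whose
patient-level frequency reaches the 3rd quartile of the per-rule frequency
distribution, ties kept.

Two-month change is computed on rule-id sets, baseline vs `t2`:
`increased = rules(t2) \ rules(t0) ≠ ∅`, `decreased = rules(t0) \ rules(t2) ≠ ∅`
(both can hold).  A swap of one anticoagulant for another that keeps the
same rule active is "no change"; this matches rule-level prevalence
accounting and is auditable, at the price of missing exotic
swap-with-new-prescription cases.  A discharge-based comparison
(`t1` vs `t2`) is available through the `baseline=` argument but is not the
default.

## Statistical layer

- **McNemar** (admission vs discharge, paired): exact two-sided binomial on
  the discordant pairs when fewer than 25 are available, continuity-
  corrected χ² otherwise; both variants can be forced.  No discordant pairs
  gives p = 1 with a warning.
- **Trend** (`t1`→`t12`): Cochran–Armitage χ² with one degree of freedom.
  Scores default to equally spaced integers over the ordered assessments —
  the design is visit-indexed, and calendar-month scores (0, 1, 5, 11) can
  be passed explicitly when elapsed time is the better axis.
- **Group comparisons**: Mann-Whitney U (two groups) or Kruskal-Wallis
  (more) for continuous data; Pearson χ² for categorical data, switching to
  Fisher's exact test for 2×2 tables whenever an expected cell is 5 or
  smaller (the boundary case is included deliberately: a degenerate table
  with expected cells exactly 5 is precisely where the exact test is
  wanted).
- **Risk-factor models**: every candidate covariate is screened with a
  single-covariate logistic fit (likelihood-ratio p for multi-level
  variables); those with P < .15 enter a multivariable maximum-likelihood
  logistic model reported as odds ratios with Wald 95% CIs, model AIC and
  the C-statistic (rank-sum AUC of fitted probabilities) with a seeded
  2000-replicate bootstrap CI.  Reference levels for dummy coding are
  age 70–79, female, site Bern and surgical admission; other categorical
  variables default to the alphabetically first level.  Perfect separation
  raises an explicit error; fewer than 10 events per parameter warns.
  No multiple-testing correction is applied anywhere; p-values are
  reported as-is and should be read accordingly.
- **Collinearity**: Pearson r (quantitative pairs), Phi (binary pairs) and
  point-biserial (mixed) coefficients above a configurable 0.7 threshold
  are reported, not resolved — choosing between correlated covariates is a
  clinical judgement that cannot be automated.  `drugs_per_day` is kept out
  of the default model covariates because `hyperpolypharmacy` is its
  threshold indicator.

## The simulator

The generator emulates the study conditions of a multicentre hospital
cohort of older adults: everyone at least 70 with at least 3 chronic
conditions and 5 chronic drugs; drugs/day log-normal with median 12
(IQR ≈ 9–15); covariate prevalences matching the published baseline table;
four sites (41% at the largest) and 1:1 randomisation to a
medication-review or usual-care arm.

Medication lists have two independent parts.  *Witness* codes realize the
interaction rules a patient is meant to trigger; *filler* codes come from a
19-code pool verified (by test and by a run-time self-check) to match no
rule group, so drug counts and DDI prevalence are controlled independently.
Witness sets for the default-injectable rules are curated to leak as little
as possible into other rules (the potassium-reducing pair is realized as
inhaled beta2 agonist + contact laxative, not as two diuretics that would
also satisfy several diuretic-containing pairwise rules); residual
emergent hits from co-injected rules are legitimate interactions and are
captured by the truth table, which is produced by running the detection
engine on the emitted codes at build time.

Baseline DDI status is Bernoulli from a logistic model on the covariates
with configurable log-odds-ratios (defaults follow the published adjusted
estimates, e.g. 1.06 for depression, 0.79 for hyperpolypharmacy); the
intercept is calibrated by root-finding so the mean probability equals the
54% prevalence target, which preserves the configured coefficients for
parameter-recovery checks.  Positive patients draw 1–4 rules (median 1)
from a weight table whose mass concentrates on the five rules that dominate
such cohorts (65, 36, 21, 12, 39 — all pharmacodynamic), reproducing their
roughly three-quarters share of all baseline hits.

Churn: at discharge the usual-care arm adds a new interacting prescription
with probability 0.16 against 0.03 in the review arm (whose additions are
balanced by deprescribing, probability 0.04 of dropping an active rule in
both arms), producing the admission-to-discharge prevalence rise that is
significant only in usual care.  At 2 months, add/drop probabilities
(means 0.225/0.37, covariate-modulated through their own logistic models
and re-calibrated to those means) yield ≈27% of patients with increased
and ≈19% with decreased DDIs; later steps use balanced small rates
(0.06/0.08) so the trend stays flat.  Follow-up snapshots are
missing-at-random per timepoint (11.5%/6%/5%), which the censoring rule
then turns into monotone attrition; informative dropout is out of scope.

What the simulator does *not* reproduce: pharmacologically realistic
co-prescription correlations beyond what rule injection induces, seasonal
or site-level prescribing styles, real ATC code frequency distributions,
adverse events and readmissions.  Green tests therefore demonstrate that
the pipeline measures correctly on data whose truth is known — not that
any particular real-world cohort has these parameter values.

## Numerical choices and degenerate inputs

Intercept calibration uses Brent root-finding on [−25, 25]; logistic fits
are Newton MLE (statsmodels) capped at 100 iterations, with |coef| > 15
treated as quasi-separation.  Empty rule tables, duplicate rule ids,
unknown timepoint tokens, empty denominators, degenerate outcomes and
single-level covariates all raise (or warn and skip) with messages naming
the offending row, field or column.  All randomness flows from explicit
seeds: the simulator requires one, the bootstrap takes one, and run
manifests record them.

## Problem sizes used in the checks

The test suite exercises: 10,000 random snapshots against the exhaustive
enumeration oracle; every discordant McNemar table up to 20 discordant
pairs; five fixed trend series against a 100,000-replicate conditional
permutation oracle (mid-p, tolerance 0.01 plus three Monte-Carlo standard
errors — the asymptotic χ² and the discrete permutation law differ by
O(1/n) at these sizes); 200 generated cohorts of 5000 patients for
coefficient recovery (±0.15 in ≥95% of replicates); and a 2000-patient
end-to-end run for the qualitative discharge-surge pattern.  These sizes
were chosen as the smallest that make the checks statistically sharp.
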
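# ddiscreen

Screening of medication lists for **potentially clinically significant
drug-drug interactions (DDIs) in older adults**, with longitudinal
point-prevalence analysis and a cohort simulator with known ground truth.

Hospitalised patients aged 70 and over with multimorbidity and polypharmacy
routinely take a dozen drugs a day, and more than half of them carry at
least one potentially clinically significant DDI.  `ddiscreen` is aimed at
pharmacoepidemiologists and clinical-pharmacy researchers who want to
quantify that burden over time: it encodes a 66-item European consensus
list of DDIs as ATC-prefix rules, screens long-format medication records at
five assessment times (admission `t0`, discharge `t1`, and 2/6/12-month
follow-up `t2`/`t6`/`t12`), and runs the accompanying statistical analyses.

## What it computes

- **Rule engine** — each consensus rule is either *pairwise* (one drug from
  each of two ATC-prefix groups, e.g. oral anticoagulant + antiplatelet) or
  a *cardinality* rule (>= k drugs from one group, e.g. >= 3 centrally-acting
  drugs).  A snapshot of codes `C` fires a pairwise rule with groups
  `G1, G2` iff distinct `a, b ∈ C` exist with `a ∈ G1`, `b ∈ G2`, and a
  cardinality rule iff `|C ∩ G| >= k`.
- **Longitudinal accounting** — eligibility requires medication data at both
  `t0` and `t1`; a patient with data at `t` but none at `t−1` is censored at
  `t−1`.  Point-prevalence at time `t` is `n_with / n_total` over
  non-censored patients, overall and stratified by mechanism
  (pharmacokinetic / pharmacodynamic), harm category, trial arm, site and
  single rule.  Between baseline and 2 months a patient's DDIs *increased*
  if a rule fires at `t2` that did not at `t0`, and *decreased* if a
  baseline rule no longer fires.
- **Statistics** — McNemar's test on paired admission/discharge DDI status
  (exact binomial below 25 discordant pairs, continuity-corrected χ²
  otherwise); Cochran–Armitage χ² test for trend over `t1…t12`;
  Mann-Whitney / Kruskal-Wallis and χ² / Fisher group comparisons; a
  univariate logistic screen at P < .15 feeding multivariable logistic
  models (odds ratios, Wald 95% CIs, AIC, C-statistic with bootstrap CI).
- **Simulator** — generates cohorts matching the study conditions (median
  age 79, median 12 drugs/day, 54% baseline DDI prevalence, discharge surge
  in the usual-care arm, ~27%/19% two-month increase/decrease, per-timepoint
  dropout) with an engine-verified truth table, so every pipeline stage is
  testable without access-restricted trial data.

## Worked example

```bash
ddiscreen report --seed 1 --n 2000 --out demo
```

simulates a 2000-patient cohort, screens it, and writes the analysis
tables.  The same flow in Python:

```python
import ddiscreen as d

rules = d.load_default_rules()          # 66 consensus rules
cohort = d.generate_cohort(d.SimulationConfig(n_patients=2000, seed=1), rules)
hits = d.screen_cohort(cohort.medications, rules)
timelines = cohort.timelines()
for tp in d.TIMEPOINTS:
    (est,) = d.point_prevalence(hits, timelines, tp)
    print(tp, f"{est.n_with}/{est.n_total} = {100 * est.proportion:.1f}%")
```

prints

```
t0 1083/2000 = 54.1%
t1 1135/2000 = 56.8%
t2 1004/1780 = 56.4%
t6 941/1669 = 56.4%
t12 896/1578 = 56.8%
```

i.e. 54.1% of patients have at least one DDI on admission; the prevalence
rises during the hospital stay (the paired McNemar test puts p well below
.001, and only in the usual-care arm) and then stays flat (trend p = .99).
Denominators shrink after discharge because censored patients leave the
risk set.  `d.most_common_rules(hits, "t0")` ranks the dominant rules — the
potassium-reducing and centrally-acting duplications, potassium-sparing
duplication, anticoagulant+antiplatelet and NSAID+SSRI pairs — which
together account for about three quarters of all baseline hits.

## Data files

`src/ddiscreen/data/ddi_rules_synthetic.csv` is the packaged, versioned
rule table (CSV with `|`-separated ATC prefixes).  The consensus source
distributes its full machine-readable encoding as restricted supplementary
material, so this table is the package's own documented reconstruction: the
sixteen rules whose published wording is fixed carry it verbatim, the
remainder are authored from standard geriatric pharmacology, and ambiguous
encoding choices are flagged in the file header.  Validation requires
exactly 66 uniquely identified rules.

## Limitations

Fixed-dose combination products are matched only by their own ATC prefixes
(no decomposition into components); route restrictions are expressed purely
through ATC class choice; distinct formulations of one substance count as
distinct codes.  See `docs/methods.md` for the full model description.
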
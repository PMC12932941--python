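# periopscreen

Rule-based perioperative eligibility screening, BPA alert-workflow
simulation, and adherence analytics on synthetic EHR cohorts.

## The problem

High-volume perioperative services cannot manually prescreen every surgical
patient for study eligibility or risk-targeted interventions. EHR-integrated
clinical decision support does this automatically: a *computable phenotype*
— a deterministic rule set over structured chart data — flags high-risk
patients, a Best Practice Advisory (BPA) alert prompts the anesthesia team,
and an embedded order pathway records whether the team followed the
recommendation. Evaluating such a system raises three questions this
package makes computable offline:

1. **Rule engine** — does a (patient, case) pair satisfy the respiratory-risk
   phenotype? Inclusion requires **at least 1 major criterion or at least 2
   minor criteria**. Majors: obstructive/restrictive lung disease (ICD-10
   code sets or preop-evaluation flags), acute respiratory infection within
   30 days, obstructive sleep apnea (G47.33 or flag), mean SpO2 < 95% in the
   12 h before surgery, airway-pathology history (> 24 ventilator hours or
   pre-admission tracheostomy), BMI > 40. Minors: > 1 documented intubation
   attempt in a prior case, scheduled duration > 120 min, upper-abdominal /
   intrathoracic / head-and-neck surgery (service + procedure-name token
   rules, or listed CPT codes), BMI > 35, serum hemoglobin < 10 g/dL within
   183 days. Hard exclusions: age < 18, pregnancy/lactation, neuromuscular
   disease, GFR < 30, sugammadex allergy, planned postoperative intubation,
   planned direct ICU admission, non-intubated airway plan, emergency
   surgery. All thresholds are strict inequalities.
2. **Alert workflow** — a BPA fires only for included, non-excluded cases at
   an eligible site during OR-pharmacy hours, in a preoperative lead window
   or during the case itself; firing is idempotent per (case, context).
   Every alerted case is classified into exactly one of five enrollment
   outcomes by precedence: misallocated (exclusion actually satisfied),
   ICU disposition, enrolled (study-pathway sugammadex ordered via the BPA),
   non-adherent with a standard-stock sugammadex bypass, or non-adherent
   with no study drug.
3. **Analytics** — allocation accuracy (PACU-restricted and all-comers),
   misallocation and ICU shares, adherence with Wilson 95% CIs overall and
   by care-team composition (full team / attending+CRNA / attending+resident
   / solo attending), attending-level adherence distributions (1.5 x IQR
   box statistics), adherent-vs-non-adherent bias tables, and a
   multivariable logistic model of provider adherence fitted on the
   rocuronium + PACU subset, reported as odds ratios with 95% CIs.

Because real perioperative EHR data cannot be shared, the package ships a
**constructive synthetic-EHR generator**: it samples the latent truth (which
criteria each case satisfies, team composition, each attending's latent
adherence propensity from team-conditional beta mixtures, covariate effects
on the log-odds scale) and then emits concrete facts — diagnoses, labs,
vitals, BMI observations, schedules, medications — that realize that truth
exactly, alongside a ground-truth ledger. Every component is therefore
testable against known truth, including deliberately boundary-adjacent
negatives (mean SpO2 exactly 95, duration exactly 120 min, BMI exactly
35/40, hemoglobin exactly 10, GFR exactly 30).

## Worked example

```bash
periopscreen pipeline --seed 7 --out demo_run
# pipeline complete: patients=1000, cases=1000, eligible=464, alerted=341, classified=341
```

`demo_run/report/report.md` then contains (seed 7, 1000 patients, default
generator settings):

```
| stage | cases |
|---|---|
| patients | 1000 |
| cases | 1000 |
| rule_eligible | 464 |
| eligible_not_excluded | 385 |
| alerted | 341 |
| enrolled | 163 |

| metric | estimate |
|---|---|
| adherence_overall | 54.9% (49.2-60.4%; 163/297) |
| adherence_all_alerted | 47.8% (42.6-53.1%; 163/341) |
| allocation_accuracy_pacu | 100.0% (98.7-100.0%; 297/297) |
| allocation_accuracy_all | 87.1% (83.1-90.2%; 297/341) |
| misallocation_rate | 0.0% (0.0-1.1%; 0/341) |
| icu_share | 12.9% (9.8-16.9%; 44/341) |
| rocuronium_share_pacu | 58.9% (53.2-64.4%; 175/297) |
```

Reading this: 464 of 1000 cases met the phenotype (≥1 major or ≥2 minor
criteria); 385 of those had no exclusion; 341 were alerted (the rest were at
an ineligible site). Of the alerted cases, 44 went to the ICU instead of the
PACU, leaving 297 appropriately allocated, of which 163 (54.9%) were
enrolled through the study pathway. Allocation accuracy is 100% among PACU
recoveries because the simulated screening system makes no documentation-
latency errors (see `docs/methods.md`); the all-comers accuracy is lower
exactly by the unpredictable-ICU share. Every denominator is printed beside
its estimate.

The same stages are available individually (`simulate`, `screen`, `alerts`,
`classify`, `report`) and as library functions; see
`docs/example_config.yaml` for a commented pipeline configuration and
`docs/data_dictionary.md` for the CSV/JSONL schemas.

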
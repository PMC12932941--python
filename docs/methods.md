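# Methods

This note documents the models, rules, defaults and numerical choices behind
`periopscreen`, and what its synthetic cohorts do and do not show about real
perioperative data.

## The eligibility phenotype

Eleven criteria (6 major, 5 minor) are evaluated per (patient, case) pair at
an `as_of` instant (default: the scheduled start). Inclusion requires at
least one major or at least two minor criteria. Every rule is deterministic
and reads only structured facts:

| criterion | tier | definition |
|---|---|---|
| obstructive/restrictive lung disease | major | diagnosis in the configured ICD-10 set (J40, J41-J41.8, J42, J43-J43.9, J44-J44.9, J45, J47-J47.9, J84.1, J84.9, D86) or a COPD / supplemental-O2 / lung-transplant preop flag |
| acute respiratory infection | major | diagnosis in the infection set with onset within 30 days before surgery, or a recent-URI flag |
| obstructive sleep apnea | major | G47.33 or a sleep-apnea flag |
| low preoperative SpO2 | major | mean of all SpO2 samples in (start − 12 h, start] strictly < 95%; **not met when the window is empty** (absence of evidence is not risk) |
| airway-pathology history | major | > 24 h pre-admission mechanical ventilation, or pre-admission tracheostomy |
| BMI > 40 | major | latest BMI observation at or before the scheduled start, strictly > 40 |
| multiple intubation attempts | minor | > 1 documented attempt in a single prior case |
| long surgery | minor | scheduled duration strictly > 120 min |
| high-risk surgical site | minor | service is not Neurosurgery and the procedure name does not mention a transplant, and at least one qualifying route matches: a General-Surgery or Thoracic-Surgery name token, the head-and-neck rule, or a listed bariatric/cholecystectomy CPT code |
| BMI > 35 | minor | as BMI > 40 with threshold 35 |
| low hemoglobin | minor | any serum hemoglobin strictly < 10 g/dL within 183 days before surgery |

Calendar phrases are fixed to day counts ("1 month" = 30 days, "6 months" =
183 days) so windows are deterministic. "BMI on admission" is
operationalized as the latest observation at or before the scheduled start,
since admission linkage is not modeled. All numeric thresholds are strict
inequalities as written; boundary values (mean SpO2 exactly 95, 120 min,
BMI exactly 35/40, hemoglobin exactly 10, GFR exactly 30, 24 ventilator
hours, age exactly 18 years) fall on the non-qualifying side, and the test
suite pins each one.

Two genuinely open readings were settled as follows and are configurable in
`resources/criteria.yaml`:

* **Head-and-neck text rule.** A head-and-neck case is disqualified only
  when the procedure name contains *both* "Mastoid" and "Tympano"
  (case-insensitive substrings) — the literal reading of the source rule; a
  stricter either-token mode is available via `head_neck_rule: either`.
* **Intubation attempts** count prior cases only, not the current case's own
  induction (which is not yet documented at alert time).
* **Preop-evaluation flags** alone satisfy their criterion without a coded
  diagnosis, mirroring the two-source layout of the rule definitions.

Exclusions: age < 18 completed years at the scheduled start, pregnancy or
lactation, neuromuscular disease, latest GFR strictly < 30 (absent GFR does
not exclude, but is logged), a normalized "sugammadex" allergy entry,
planned postoperative intubation, planned direct ICU admission,
non-intubated airway plan, and emergency surgery. An *unplanned* ICU
transfer is not an exclusion at alert time — it is unknowable
preoperatively — and instead becomes a distinct enrollment outcome.

ICD-10 matching: codes are normalized (trim, uppercase, dot removal); a bare
root matches itself and every descendant; a range like `J41-J41.8` is
per-category and includes descendants of its upper endpoint (`J41.83` in,
`J41.9` out); `J09.x` is an explicit all-descendants wildcard. Unparseable
tokens fail at resource-load time; malformed codes in patient data are
skipped with a warning and never treated as met.

## Alert workflow

`should_fire` is a pure function of (case, decision, availability config,
polling instant) plus the alert ledger: it fires only for included,
non-excluded decisions at an eligible site during pharmacy hours, with the
instant inside the preoperative lead window (context `preop`) or the
scheduled case interval (context `intraop`). The ledger deduplicates per
(case, context), so replaying a poll stream yields an identical alert set.
Non-firing polls return a stable reason code (`ineligible`, `excluded`,
`site`, `hours`, `window`, `duplicate`). Pharmacy hours default to
07:00–22:00 and the lead window to 7 days; both are configuration — the
production values they stand in for are not published. Downstream metrics
count *cases*, not alerts, so a case alerted in both contexts is counted
once.

Enrollment classification is total and mutually exclusive by precedence:
misallocated-exclusion > ICU disposition > enrolled > stock-sugammadex
bypass > no study drug. Misallocation outranks ICU so the two error buckets
never double-count a case. The classifier takes the exclusion set as
re-evaluated at classification time with full data; in production the
difference between that set and the alert-time snapshot (documentation
latency) is what produces misallocated alerts.

## Analytics

* **Proportions** carry exact numerator/denominator and a 95% CI — Wilson by
  default (better small-sample behavior), normal approximation available for
  comparison with conventionally reported intervals. Denominators are
  printed in every report.
* **Metric denominators.** Allocation accuracy (PACU) = appropriately
  allocated alerts / alerts to non-ICU cases; allocation accuracy (all) =
  the same numerator over all alerts. Adherence = enrolled / appropriately
  allocated PACU-recovering alerts; because published cohort summaries also
  use an all-alerted denominator, `adherence_all_alerted` is exposed
  alongside, explicitly labelled.
* **Provider distributions** use per-(attending, team) adherence among
  appropriately allocated cases, quartiles by linear interpolation (numpy
  default, type 7) and whiskers at 1.5 x IQR; attendings under a
  configurable minimum case count are excluded from the box statistics and
  flagged in the provider table.
* **Bias table**: Welch t-test (declared normal continuous), Mann-Whitney U
  (skewed continuous), chi-square for categorical with Fisher's exact when
  any expected cell of a 2x2 table is below 5. P-values are two-sided and
  deliberately unadjusted for multiplicity (matching how such descriptive
  tables are conventionally presented); the output says so. Groups with
  fewer than two observations on a continuous variable are skipped and
  flagged. Mortality-style very-low-frequency outcomes should be read as
  counts, not tests.
* **Adherence model**: maximum-likelihood logistic regression
  (statsmodels), outcome enrolled vs non-adherent, restricted to alerted
  cases that received rocuronium and recovered in the PACU so that
  postoperative disposition cannot structurally confound adherence.
  Categorical covariates are treatment-coded (team reference level:
  full team). Wald 95% CIs; non-convergence and likely complete separation
  (|coefficient| > 15) are reported as structured warnings, never silently
  dropped. ASA status is emitted by the generator as an optional field and
  may be added as a covariate, but is not in the default set since it is
  often unavailable at ordering time in practice.

## The synthetic generator

Generation is constructive: latent truth first, then facts that realize it,
plus a ground-truth ledger — so generator/engine agreement is an exact
invariant, not a statistical one, and boundary-adjacent negatives can be
produced deliberately (`boundary_negative_rate`, default 0.15).

Defaults describe a plausible large academic perioperative cohort and are
**placeholders where no published value exists** (criterion and exclusion
prevalences in particular; institution-specific truth is unpublished):

* Team mix 8.4% full team / 25.5% attending+CRNA / 54.3% attending+resident
  / 11.8% solo, back-derived from reported stratum CI widths at the
  ~10,600-case scale.
* Adherence propensities per team are beta (or two-component beta) mixtures
  whose means emulate reported stratum adherence (57.4 / 56.9 / 52.6 /
  42.2%); the solo stratum is bimodal (62.8% weight on a low-adherence
  component), reproducing the characteristic wide, two-cluster solo provider
  distribution. Each attending draws one latent propensity per team
  category.
* Covariate effects are applied on the log-odds scale with covariates
  centered at their configured prevalences: this keeps team-stratified
  marginal adherence at the mixture mean while leaving odds ratios
  unchanged. Defaults mirror reported workflow effects (long surgery +0.30,
  patient-related delay +0.31, scheduling delay +0.25, staff-related delay
  −0.545, low hemoglobin +0.846, low SpO2 −0.734).
* Disposition mix (86.1% PACU / 4.0% planned ICU / 9.9% unplanned ICU) is
  chosen so that, conditional on an alert firing, unplanned ICU transfers
  are ~10.3% of alerted cases. Rocuronium probability 0.686; 80% of
  non-adherent alerted cases receive a stock-sugammadex bypass.
* One RNG stream per record type, all spawned from the master seed:
  identical configs give bitwise-identical serialized cohorts, and adding
  draws to one stage never perturbs another.

**What the simulation does not emulate.** The package's own screening is
exact, so simulated cohorts contain no misallocated alerts
(misallocation_rate = 0 and PACU-restricted allocation accuracy = 100% by
construction); real systems misallocate a few percent of alerts through
documentation latency and upstream data errors. The classifier and metrics
fully support the misallocated category (exercised by hand-built fixtures in
the tests). Likewise absent: ICD code-frequency realism beyond the
criterion sets, multi-admission longitudinal histories, free-text nuance,
and alert-dismissal behavior. Passing tests therefore demonstrate internal
correctness and statistical calibration of the machinery — not that any
particular institution's rates will be reproduced.

## Designed recovery experiments (test suite)

* **Team-propensity recovery** uses covariate effects off, an equal team mix
  and 4,000 attendings at n = 20,000, so each stratum's adherence is exactly
  binomial around its mixture mean (one case per provider on average removes
  clustering); the check is a simultaneous 95% binomial bound (Bonferroni
  over the four strata).
* **Odds-ratio recovery** injects +0.30 log-odds for long surgery with
  near-degenerate propensity spread (Beta(300, 300)) and forced eligibility,
  so the marginal logistic OR is not attenuated by provider heterogeneity;
  recovery is checked within 10% of exp(0.30). Under the *default* broad
  propensity mixtures the marginal OR is attenuated (≈1.2 rather than 1.35)
  — expected behavior of a population-averaged estimate under cluster
  heterogeneity, visible in the acceptance-script output.
* **Null coverage**: 200 seeded null fits at n = 5,000; Wald CIs cover
  OR = 1 at ≥ 93% pooled over covariates.
* **Mann-Whitney power** is compared against an independently coded
  Monte-Carlo oracle on the *same* 2,000 simulated dataset pairs, isolating
  the code path as the only source of difference.

Problem sizes throughout (10,000-case oracle equivalence, 5 seeds of 10,000
for ground-truth consistency, 20,000 for recovery, 200 null fits) were
chosen to make the statistical bounds sharp at modest runtime.

## Known limitations

* Timestamps are timezone-naive local clinical time; DST and cross-site
  clock semantics are out of scope.
* Only ICD-10 is matched; legacy ICD-9 histories are not.
* The surgical-site rule is substring-token matching, not NLP; procedure
  names outside the configured token vocabulary will not qualify.
* The adherence model is population-averaged; no provider random effects are
  fitted, so conditional (within-provider) effects are attenuated in its
  estimates under heterogeneous propensities.
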
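# Data dictionary

Two interchange formats are supported. Timestamps are ISO-8601 at second
resolution, timezone-naive local clinical time; dates are ISO calendar
dates; booleans are `true`/`false`; floats round-trip exactly (written via
`repr`). Multi-valued CSV fields are semicolon-joined and must not contain
`;`. Empty string means absent for optional fields.

## JSONL (canonical)

* `patients.jsonl` — one JSON object per line matching `PatientRecord`
  (nested `diagnoses`, `labs`, `vitals`, `bmi_observations`,
  `airway_history`); keys sorted, set-valued fields serialized sorted.
* `cases.jsonl` — one object per line matching `SurgicalCase` (nested
  `staffing`, `meds`, `outcomes`).

## CSV (normalized tables)

### patients.csv
| column | type | notes |
|---|---|---|
| patient_id | string | unique |
| birth_date | date | |
| sex | enum | female / male / other |
| pregnant_or_lactating | bool | |
| allergies | string list | normalized drug names, `;`-joined |
| preop_eval_flags | enum list | copd, supplemental_o2, lung_transplant, recent_uri, sleep_apnea |
| neuromuscular_disease | bool | |
| gfr_latest | float? | mL/min/1.73 m²; empty = never measured |
| vent_hours_pre_admission | float | max pre-admission ventilator hours |
| tracheostomy_pre_admission | bool | |
| prior_case_max_intubation_attempts | int | |

### diagnoses.csv
`patient_id`, `icd10` (raw code; normalized on read), `onset_date` (date).

### labs.csv
`patient_id`, `analyte` (hemoglobin_serum | other; g/dL for hemoglobin),
`value` (float), `collected_at` (timestamp).

### vitals.csv
`patient_id`, `kind` (spo2), `value` (percent, 0-100), `observed_at`.

### bmi_observations.csv
`patient_id`, `observed_at` (timestamp), `value` (kg/m², > 0).

### cases.csv
| column | type | notes |
|---|---|---|
| case_id | string | unique |
| patient_id | string | must resolve in patients |
| site | string | site identifier |
| scheduled_start | timestamp | |
| scheduled_duration_min | int | > 0 |
| service | string | e.g. "General Surgery" |
| procedure_name | string | free text |
| cpt_codes | string list | `;`-joined |
| emergency | bool | |
| airway_plan | enum | intubated_general / non_intubated |
| planned_postop_intubation | bool | |
| asa_status | int? | 1-5, optional |
| attending_id | string | |
| crna_present / resident_present | bool | team roster |
| delays | enum list | patient_related, scheduling, staff_related, none |
| disposition | enum | pacu / icu_direct / icu_unplanned_transfer / floor |
| unexpected_icu_transfer | bool | outcome |
| reintubation | bool | outcome |
| pacu_los_min | float? | absent for icu_direct |
| min_spo2 | float? | percent |
| death | bool | outcome |

### meds.csv
`case_id`, `drug` (rocuronium / sugammadex / neostigmine / other), `source`
(study_pathway / standard_stock / n/a), `administered_at`, `ordered_via_bpa`
(bool). Constraint: `study_pathway` implies sugammadex with
`ordered_via_bpa = true`.

## Generated alongside (not read back)

* `ground_truth.csv` — the simulator's ledger: per-case latent criterion and
  exclusion bits, team, intended alert/adherence, propensities.
* `sim_config.json` — the full generator config including the seed, so a
  fixture regenerates exactly.
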
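# Respiratory-risk eligibility criterion definitions (versioned resource).
#
# This file externalizes every code set, threshold, lookback window and text
# rule the criteria engine evaluates, so an audit can diff the deployed rule
# set against its clinical source definition without reading code.
#
# Inclusion logic: at least 1 major criterion OR at least 2 minor criteria.
# All numeric thresholds are strict inequalities as written.

version: "1.0"

code_sets:
  obstructive_restrictive_lung_disease:
    # Bronchitis, emphysema, COPD, bronchiectasis, pulmonary fibrosis,
    # sarcoidosis of lung.
    [J40, J41-J41.8, J42, J43-J43.9, J44-J44.9, J45, J47-J47.9, J84.1, J84.9, D86]
  acute_respiratory_infection:
    # Acute nasopharyngitis, acute URIs, influenza, pneumonia, bronchitis.
    [J00, J06-J06.9, J09, J09.x, J10-J10.89, J12-J12.9, J15-J15.9, J16-J16.8, J17, J18-J18.9, J20-J20.9]
  obstructive_sleep_apnea:
    [G47.33]

windows:
  acute_infection_days: 30      # "within 1 month of surgery"
  hemoglobin_days: 183          # "in the past 6 months"
  spo2_hours: 12                # "in the 12 hours prior to surgery"

thresholds:
  spo2_mean_pct: 95.0           # mean SpO2 strictly below
  bmi_major: 40.0               # BMI strictly above
  bmi_minor: 35.0
  hemoglobin_g_dl: 10.0         # serum hemoglobin strictly below
  long_surgery_min: 120         # scheduled duration strictly above
  ventilator_hours: 24.0        # pre-admission ventilation strictly above
  intubation_attempts: 1        # documented attempts in one case strictly above
  gfr_exclusion: 30.0           # GFR strictly below excludes
  adult_age_years: 18           # full years at scheduled start; below excludes

surgical_site:
  # "Upper abdominal / intrathoracic / head and neck surgery" minor criterion.
  # Required: service is not the excluded service AND the procedure name does
  # not mention a transplant. Then at least one qualifying route must match:
  # a service-specific name token, the head-and-neck rule, or a listed CPT.
  excluded_service: Neurosurgery
  transplant_token: transplant
  service_tokens:
    General Surgery: [Gastric, Liver, Pancreas, Hepat, Chole]
    Thoracic Surgery: [Pulm, Resection, Esoph, VATS, Lobe, Thoracotomy]
  head_neck_service: Head and Neck
  head_neck_forbidden_tokens: [Mastoid, Tympano]
  # "both": the case is disqualified only when the name contains BOTH
  # forbidden tokens (literal reading); "either": one token suffices.
  head_neck_rule: both
  cpt_codes: ["43775", "47562", "43644", "43774"]
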
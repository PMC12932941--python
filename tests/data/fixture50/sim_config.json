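{
  "n_patients": 50,
  "seed": 50,
  "criterion_prevalences": {
    "obstructive_restrictive_lung_disease": 0.12,
    "acute_respiratory_infection": 0.03,
    "obstructive_sleep_apnea": 0.15,
    "low_preop_spo2": 0.04,
    "airway_pathology_history": 0.02,
    "bmi_over_40": 0.08,
    "multiple_intubation_attempts": 0.01,
    "long_surgery": 0.45,
    "high_risk_surgical_site": 0.2,
    "bmi_over_35": 0.18,
    "low_hemoglobin": 0.06
  },
  "exclusion_prevalences": {
    "age_lt_18": 0.005,
    "pregnant_lactating": 0.01,
    "neuromuscular_disease": 0.01,
    "gfr_lt_30": 0.02,
    "sugammadex_allergy": 0.002,
    "planned_postop_intubation": 0.02,
    "non_intubated": 0.04,
    "emergency": 0.03
  },
  "site_mix": {
    "main_campus": 0.55,
    "west_campus": 0.35,
    "community": 0.1
  },
  "eligible_sites": [
    "main_campus",
    "west_campus"
  ],
  "team_mix": {
    "full_team": 0.084,
    "attending_crna": 0.255,
    "attending_resident": 0.543,
    "solo_attending": 0.118
  },
  "delay_probabilities": {
    "patient_related": 0.08,
    "scheduling": 0.1,
    "staff_related": 0.06
  },
  "disposition_model": {
    "pacu": 0.861,
    "icu_direct": 0.04,
    "icu_unplanned_transfer": 0.099
  },
  "rocuronium_probability": 0.686,
  "stock_bypass_share": 0.8,
  "adherence_propensities": {
    "full_team": {
      "components": [
        [
          1.0,
          2.2,
          1.633
        ]
      ]
    },
    "attending_crna": {
      "components": [
        [
          1.0,
          3.0,
          2.272
        ]
      ]
    },
    "attending_resident": {
      "components": [
        [
          1.0,
          2.8,
          2.523
        ]
      ]
    },
    "solo_attending": {
      "components": [
        [
          0.628,
          1.6,
          5.5
        ],
        [
          0.372,
          5.5,
          1.8
        ]
      ]
    }
  },
  "covariate_effects": {
    "long_surgery": 0.3,
    "delay_patient_related": 0.31,
    "delay_scheduling": 0.25,
    "delay_staff_related": -0.545,
    "low_hemoglobin": 0.846,
    "low_preop_spo2": -0.734
  },
  "n_attendings": 120,
  "boundary_negative_rate": 0.15,
  "emit_asa": true,
  "base_date": "2023-01-02",
  "schedule_span_days": 600
}
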
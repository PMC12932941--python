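# Example pipeline configuration for `periopscreen pipeline --config ...`.
# Every key is optional; omitted keys use the documented defaults.

seed: 42          # master seed; every RNG stream derives from it
format: jsonl     # dataset interchange format: jsonl | csv

# Generator overrides (see SimConfig). Defaults are placeholders for a
# large academic perioperative cohort; override them to match your setting.
sim:
  n_patients: 2000
  # criterion_prevalences:             # probability each criterion is true
  #   obstructive_sleep_apnea: 0.15
  #   long_surgery: 0.45
  # team_mix:                          # must sum to 1
  #   full_team: 0.084
  #   attending_crna: 0.255
  #   attending_resident: 0.543
  #   solo_attending: 0.118
  # adherence_propensities:            # per-team beta mixtures (weight, a, b)
  #   solo_attending:
  #     components: [[0.628, 1.6, 5.5], [0.372, 5.5, 1.8]]
  # covariate_effects:                 # log-odds effects on adherence
  #   long_surgery: 0.30
  # boundary_negative_rate: 0.15       # boundary-adjacent negatives

# Where and when BPA alerts may fire.
availability:
  eligible_sites: [main_campus, west_campus]
  pharmacy_open: "07:00"
  pharmacy_close: "22:00"
  preop_lead_days: 7

min_provider_cases: 5   # minimum cases for an attending to enter box stats
make_figure: true       # write the provider-adherence box plot (PNG)
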
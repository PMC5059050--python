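# Study configuration template for `rxpersist full --config study_config.yaml`
# (also accepted by `rxpersist analyze` and StudyConfig.from_yaml).
# Unknown keys are rejected, never silently ignored.

# --- episode construction ---------------------------------------------------
grace_days: 30              # max days without supply before discontinuation
followup_days: 730          # study horizon (2 years, non-leap convention)
event_at: supply_end        # date events at end of supply; or supply_end_plus_grace
switch_handling: event      # switchers count as discontinuation events; or censor

# --- survival modelling -----------------------------------------------------
ties_method: efron          # or breslow (day-resolution data produce many ties)
readout_days: [365, 730]    # Kaplan-Meier persistence readouts

# --- auxiliary windows ------------------------------------------------------
bp_switch_window_days: 182      # 26 weeks before a switch for the BP audit
n_other_drugs_window_days: 365  # lookback for the other-drug count covariate

# optional extra dosage-grammar rules, one "phrase<TAB>multiplier" per line
# dosage_grammar_file: extra_dosage_rules.tsv

# --- optional eligibility window (dates ISO 8601; omit to accept any index) --
# enrollment_start: 2006-01-01
# enrollment_end: 2007-12-31

km_plot: false              # also write km_curves.png

# --- synthetic cohort (used by `full`, or `simulate`) ------------------------
simulation:
  n_patients: 2000
  seed: 11
  followup_days: 730
  grace_days: 30
  refill_cycle_days: 90.0   # ~3-month prescriptions
  missing_dosage_prob: 0.006
  switch_prob: 0.45         # of ended episodes followed by an other-class fill
  addon_prob: 0.08
  death_prob: 0.005
  hosp_prob: 0.15
  unit_bag_prob: 0.0054
  # piecewise-constant baseline discontinuation hazard per day:
  # ~57% latent persistence at 1 year, ~43% at 2 years
  baseline_hazard: [[0, 0.001539], [365, 0.000772]]
  # true log-hazard ratios, class initiation probabilities, covariate
  # marginals etc. all have documented defaults; override any field of
  # SimulationConfig here, e.g.:
  # true_loghr: {male: 0.25, age_30_49: 0.40, ...}
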
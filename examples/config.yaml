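# A full maturity experiment: one simulated myeloma-like cohort,
# locks at maximum follow-up 3/6/8/10/13 years, 16-model roster.
seed: 42
max_followups: [3, 6, 8, 10, 13]
evaluation_horizon: 14
lifetime_horizon: 35
reference_followup: 25
cohorts:
  - label: mm-sim
    n_subjects: 300
    enroll_start: 2002.72
    enroll_end: 2007.54
    ltfu_rate: 0.0
    survival_model:
      name: piecewise
      rates: [0.10, 0.35, 0.12]
      knots: [1.5, 5.0]
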
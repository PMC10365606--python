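activations:
  support_from_superior: 1
  training_and_specialization: 1
expected_outcomes:
  confirming_communication: 1
  functional_ability_autonomy: 1
  job_satisfaction: 1
name: training_and_supervision
notes: Staff training improves the confirming staff-user relationship and, through
  it, user functional ability; supervisor support improves job satisfaction.
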
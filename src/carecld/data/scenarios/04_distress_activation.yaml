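activations:
  distress: 1
expected_outcomes:
  burnout: 1
  health_safety_risk: 1
  job_involvement: -1
  physio_mental_health_response: 1
  quality_of_care: -1
name: distress_activation
notes: Distress degrades staff health (risk and burnout rise), job involvement and
  quality of care.
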
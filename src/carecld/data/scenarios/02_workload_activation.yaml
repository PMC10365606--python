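activations:
  workload: 1
expected_outcomes:
  decision_demands: 1
  distress: 0
  job_satisfaction: -1
  needs_met: -1
  provision_of_care_and_services: -1
  quantitative_demands: 1
  role_conflict: 1
  work_pace: 1
name: workload_activation
notes: Demand elements rise and provision falls; distress stays unmodulated because
  the equal-weight scheme cancels the overload and underload channels.
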
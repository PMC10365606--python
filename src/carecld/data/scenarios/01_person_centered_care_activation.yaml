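activations:
  person_centered_care: 1
expected_outcomes:
  functional_ability_autonomy: 1
  health_safety_risk: -1
  needs_met: 1
  provision_of_care_and_services: 1
  quality_of_life_user: 1
  trust_in_home_care_staff: 1
name: person_centered_care_activation
notes: 'Reablement: activates delivery and quality of care, improves user quality
  of life, reduces staff health and safety risks.'
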
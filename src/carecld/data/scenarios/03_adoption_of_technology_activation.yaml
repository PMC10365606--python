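activations:
  adoption_of_technology: 1
expected_outcomes:
  complexity_of_work_tasks: 1
  equipment_problems: 1
  person_centered_care: 1
name: adoption_of_technology_activation
notes: Technology adoption supports person-centred care but raises task complexity
  and equipment problems.
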
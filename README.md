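# carecld

A toolkit for qualitative systems modelling of home care services with
**causal loop diagrams (CLDs)**: signed directed graphs whose nodes
("elements") are system variables — staff workload, distress, needs met,
quality of care — and whose edges ("connections") carry a polarity,
`+1` when an increase in the source drives the target up and `-1` when it
drives it down.

It is written for health-services and systems researchers who want to go
beyond drawing a CLD: validate it, enumerate its feedback loops, simulate
what-if interventions at the sign level, and verify the model against
narrative intervention outcomes — all scriptably and reproducibly.

## What it does

- **Model core** — load/write CLDs as CSV table pairs, Kumu-style JSON or
  Graphviz DOT, with strict validation (referential integrity, no
  self-loops, no duplicate edges, a closed six-category scheme: stress,
  home care staff, home care user, organization, social support,
  societal).
- **Built-in home-care model** — a 76-element, 108-connection CLD of
  Swedish home care centred on the demand–control work-stress model
  (distress arises from work *overload* when demand exceeds control and
  from *underload* when control exceeds demand), together with five
  curated intervention scenarios (person-centred reablement care,
  workload, technology adoption, distress, staff training/supervision).
- **Loop analysis** — every simple cycle, classified *reinforcing* (sign
  product +1, amplifies change — a candidate leverage point) or
  *balancing* (sign product −1, counteracts change).
- **Qualitative simulation** — clamped-source synchronous sign
  propagation with equal edge weights: states in {−1, 0, +1}, each
  element's next state is the sign of the polarity-weighted sum of its
  parents. Opposing influences cancel to 0 ("unmodulated").
- **Verification harness** — replay a scenario and score the fraction of
  expected signed outcomes the model recovers.
- **Network metrics** — degree, betweenness, closeness, eigenvector
  centrality, downstream reach, and a composite leverage ranking.
- **Synthetic generator** — seeded random CLDs with realistic dimensions
  (122 elements / 223 connections across the six categories by default)
  for testing and robustness analysis.

## Worked example

Enumerate the feedback loops of the built-in model:

```sh
$ carecld loops --model fixture | head -6
loop_id	length	polarity	elements
0	2	balancing	needs_met|provision_of_care_and_services
1	3	reinforcing	adverse_events_progression|need_for_care|needs_met
2	3	reinforcing	delivery_informal_care|needs_met|qol_informal_caregiver
3	3	balancing	needs_met|stress_of_conscience|provision_of_care_and_services
4	4	reinforcing	ability_to_cope|control|overload|distress
```

Loop 0 is the service-delivery thermostat: provision raises "needs met",
which relaxes the demand for provision. Loop 1 is the vicious circle of
inadequate care: unmet needs cause adverse events or disease progression,
raising the need for care and making needs still harder to meet. Loop 4
is the stress spiral: distress erodes coping, coping sustains control,
and low control raises work overload, feeding distress back.

Verify the five intervention scenarios against their expected outcomes:

```sh
$ carecld verify --model fixture --scenarios src/carecld/data/scenarios
person_centered_care_activation: agreement=1.000 (6/6)
  functional_ability_autonomy: expected +1, simulated +1  [ok]
  health_safety_risk: expected -1, simulated -1  [ok]
  needs_met: expected +1, simulated +1  [ok]
  ...
workload_activation: agreement=1.000 (8/8)
  distress: expected +0, simulated +0  [ok]
  ...
overall agreement: 1.000
```

Every expectation matches, so the exit code is 0 (it would be 2 below the
`--threshold`, default 1.0). Note `distress: +0` under the workload
activation: with equal weights, workload raises job demand, which pushes
overload up and underload down by exactly the same amount — the two
distress channels cancel, so the linear scheme leaves distress
unmodulated. That is the expected signature of a nonlinear (U-shaped)
demand–control interaction that sign propagation cannot express.

The same pipeline is available as a library:

```python
from carecld import build_homecare_fixture, fixture_scenarios, verify_suite

model = build_homecare_fixture()
summary = verify_suite(model, fixture_scenarios())
print(summary.overall_agreement)   # 1.0
```

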
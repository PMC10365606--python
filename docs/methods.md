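# Methods

## The model class

A causal loop diagram (CLD) here is a simple signed digraph
`G = (V, E, σ)` with `σ : E → {+1, −1}`. Elements carry a label, an
optional description and evidence references, and exactly one of six
categories (stress, home care staff, home care user, organization, social
support, societal) reflecting the conceptual level of the variable.
Structural invariants, enforced by validation: element ids are unique
lowercase slugs; every connection endpoint exists; no self-loops (loop
semantics are reserved for multi-element cycles); at most one connection
per ordered pair, because silently merging duplicates could flip a
polarity. Isolated elements are legal but flagged as warnings.

Polarity is stored as ±1 integers so that cycle polarity is a plain
product of signs, and a serialized model round-trips exactly through the
CSV table pair and the JSON document (DOT is export-only).

## The built-in home-care model

The fixture transcribes the named core of a published qualitative systems
model of Swedish home care: 76 elements and 108 connections spanning all
six categories. At its centre sits the demand–control model of work
stress: job demand raises work overload (`+`) and lowers work underload
(`−`), control does the exact opposite, both overload and underload feed
distress (`+`), distress erodes the ability to cope (`−`), and coping
sustains control (`+`). This linearization deliberately replaces the
U-shaped demand–control interaction; its signature is analysed below.

Each connection is provenance-tagged in `evidence_refs`:

- `reported` — the direction is stated in the source narrative;
- `derived` — the wiring or sign is not stated; the value used is the
  minimal assignment that reproduces every stated feedback-loop polarity
  and every stated intervention outcome. Each derived edge carries an
  inline code comment naming the behaviour that requires it.

Three transcription choices were genuinely open and are worth recording.
"Provision of care and services" and "delivery of care and services" are
treated as a single element. The second balancing loop through stress of
conscience is closed with `stress_of_conscience →
provision_of_care_and_services (+)` (conscience pressure pushes delivery
back up), one admissible closure among several. Staff health outcomes
under the distress activation are encoded in risk polarity (health *risk*
and burnout rise) rather than as a drop in a "health" element — the
direction of meaning is preserved, the verbal sign is inverted.

## Qualitative simulation

States live in `{−1, 0, +1}`; all connections have equal weight.
A scenario clamps its activated elements (*sources*) to ±1 for the whole
run. All other elements start at 0 and update synchronously:

    raw_t(v)   = Σ_{(u→v) ∈ E} σ(u→v) · s_t(u)
    s_{t+1}(v) = sign(raw_t(v)),   sign(0) = 0

Two per-element summaries are reported:

- **first response** — the first nonzero state attained (0 if none):
  the initial directional shock, the quantity intervention narratives
  describe, and the default for verification;
- **fixed point** — the converged state. Balancing loops often prevent
  convergence; the synchronous dynamics then enter a periodic orbit,
  which is detected by state-hashing, and every element whose state
  varies over the orbit is flagged `ambiguous` with fixed point 0.

`max_iter` defaults to `2·|V|`; non-convergence is a reported outcome,
not an error. Status flags: `source`, `changed` (nonzero first
response), `unchanged` (reachable but never nonzero), `ambiguous`,
`unreached` (no directed path from any source). The dynamics are odd in
the activations (negating every activation negates everything), fully
deterministic, and seed-free.

### The cancellation signature

Because demand and control drive overload and underload in exactly
opposite ways, `raw(overload) = −raw(underload)` under any activation
confined to job demand and control, so the two distress inputs cancel at
every iteration and distress stays 0. The equal-weight linear scheme
*cannot* express the U-shaped demand–control interaction; the test suite
checks this exhaustively over all eight activation sign combinations.
This is a documented property of the method, not a bug, and a node-level
nonlinear rule is left as an extension point.

### The path-sum oracle and its exact regime

`path_sum_oracle` recomputes, per element, the sign of the sum over all
simple directed paths from the sources of (activation × product of edge
signs), never letting a path pass through another clamped source. On
models where each element is reached by at most one path (trees), this
provably equals the propagation first response, and the property suite
checks the two against an independent brute-force enumerator there.

On general DAGs the two summaries can legitimately differ, in two ways.
First, arrival order: with edges `a→d (+)`, `a→b (+)`, `b→d (−)`, the
short path registers first response +1 at t=1, while the full path sum is
0 (the fixed point also relaxes to 0). Second, sign flattening: a node
whose raw input is ±2 transmits only ±1, so path multiplicities are lost
before later conflicts resolve. Both effects are frozen in regression
tests, and the acceptance script reports the measured full-agreement
fraction over 200 random DAGs rather than asserting a false theorem.

## Verification

A scenario's expectations are signed outcomes `{−1, 0, +1}` per element.
Verification propagates the scenario and scores
`agreement = matches / expectations-with-element-present`. Expected or
activated elements absent from the model are reported in dedicated fields
and excluded from the denominator — models evolve and elements get
renamed, so silent skips and spurious failures are equally misleading. A
suite's overall agreement is the unweighted mean over scenarios with at
least one scoreable expectation. Agreement is invariant under reordering
of scenarios and expectations.

## Loop analysis and leverage

Simple cycles are enumerated via depth-limited simple-cycle search on the
digraph, deduplicated by canonical rotation (lexicographically smallest
element first) and reported sorted by (length, elements). A configurable
cycle-count cap (default 10^6) guards against pathological dense graphs;
hitting it logs a warning and truncates. Polarity: reinforcing iff the
product of edge signs is +1.

Leverage ranking is this package's own composite, ordered
lexicographically by (reinforcing-loop participation, total loop
participation, downstream reach), ties broken by element id. The
rationale: membership in reinforcing loops is the classic marker of a
leverage point, loop participation generally second, and sheer downstream
reach a tie-breaker for acyclic regions.

Centralities are computed on the unsigned digraph: degrees, unnormalized
betweenness on shortest directed paths, outward closeness (computed on
the reversed graph), eigenvector centrality on the undirected underlying
graph (well defined even on acyclic models; exact zeros are restored for
isolated nodes), and downstream reach as a descendant count.

## Synthetic models

The generator emulates only the *statistical shape* of the full published
model: category sizes (stress 6, home care staff 44, home care user 28,
organization 26, social support 13, societal 5 — 122 elements), 223
connections, sparsity, presence of feedback cycles, and a minority of
negative edges. Defaults: `negative_fraction = 0.25` (the published
narrative does not state its negative-edge count; 0.25 is a package
choice, configurable and not a claim about the source model) and
`ensure_cycles = 3` planted short cycles alternating reinforcing and
balancing polarity. Edge placement is uniform over allowed ordered
pairs; all randomness flows from a single integer seed through one
`numpy` generator, and equal specs yield byte-identical serialized
models.

What synthetic models do **not** emulate: the real model's degree
distribution, motif content, category-to-category wiring, or any domain
semantics. Tests passing on synthetic models therefore demonstrate
algorithmic correctness and robustness at realistic scale, not substantive
conclusions about home care; those rest on the curated fixture.

`perturb_model` supports robustness studies: seeded polarity flips and
target rewires that preserve source endpoints and structural validity.

## Problem sizes and determinism

All routine analyses are desk-scale: the fixture has 108 edges and ten
feedback loops; property suites use random graphs of up to ~15 nodes with
hundreds of replicates, and oracle comparisons use 200 random DAGs of 4 to
12 nodes. Everything outside the synthetic generator is deterministic
with no seed at all; CLI outputs are byte-stable across runs.

## Known limitations

- Sign propagation is qualitative: no weights, delays, stocks or flows,
  and no nonlinear node rules (see the cancellation signature above).
  Quantitative system-dynamics translation is out of scope.
- First-response semantics describe the initial shock; long-run
  behaviour in the presence of balancing loops is summarised only as
  ambiguity flags at the fixed point.
- The fixture is a faithful subset of the full published model, not a
  reconstruction of it; derived-tagged edges are reasoned gap-fills and
  are machine-identifiable for sensitivity analysis.
- The leverage composite and the agreement fraction are this package's
  operationalizations of narrative concepts; alternative definitions are
  easy to swap in via the underlying loop and reach tables.
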
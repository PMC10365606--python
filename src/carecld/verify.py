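"""Qualitative scenario verification.

The verification harness replays a curated intervention scenario on a
model and scores how well the simulated signed responses agree with the
scenario's expected outcomes — the computational analogue of comparing a
causal-pathway narrative ("the intervention increased X and reduced Y")
against the model's cascade reaction.

Expectations are scored against ``first_response`` semantics by default:
intervention narratives describe initial directional responses, which
balancing feedback may later cancel at the fixed point.

Expectations (or activations) naming elements absent from the model are
reported explicitly and excluded from the agreement denominator — models
evolve and elements get renamed, so a silent skip or a spurious mismatch
would both be misleading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .model import CLDModel
from .simulate import Scenario, SimulationResult, propagate


@dataclass(frozen=True)
class ExpectationRow:
    element: str
    expected: int
    simulated: int
    match: bool


@dataclass
class VerificationReport:
    """Per-scenario agreement between simulated and expected signs."""

    scenario: str
    rows: list[ExpectationRow]
    agreement: float | None
    unmatched_expectations: list[str] = field(default_factory=list)
    missing_activations: list[str] = field(default_factory=list)
    result: SimulationResult | None = None

    @property
    def n_matches(self) -> int:
        return sum(r.match for r in self.rows)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "agreement": self.agreement,
            "rows": [
                {"element": r.element, "expected": r.expected,
                 "simulated": r.simulated, "match": r.match}
                for r in self.rows
            ],
            "unmatched_expectations": list(self.unmatched_expectations),
            "missing_activations": list(self.missing_activations),
        }


@dataclass
class VerificationSummary:
    """Suite-level roll-up: one report per scenario plus the mean agreement."""

    reports: list[VerificationReport]
    overall_agreement: float | None

    def to_dict(self) -> dict:
        return {
            "overall_agreement": self.overall_agreement,
            "scenarios": [r.to_dict() for r in self.reports],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = []
        for r in self.reports:
            agreement = "n/a" if r.agreement is None else f"{r.agreement:.3f}"
            lines.append(f"{r.scenario}: agreement={agreement} "
                         f"({r.n_matches}/{len(r.rows)})")
            for row in r.rows:
                mark = "ok" if row.match else "MISMATCH"
                lines.append(f"  {row.element}: expected {row.expected:+d}, "
                             f"simulated {row.simulated:+d}  [{mark}]")
            for el in r.unmatched_expectations:
                lines.append(f"  {el}: not in model (excluded)")
        overall = ("n/a" if self.overall_agreement is None
                   else f"{self.overall_agreement:.3f}")
        lines.append(f"overall agreement: {overall}")
        return "\n".join(lines)


def verify_scenario(
    model: CLDModel,
    scenario: Scenario,
    semantics: str = "first",
    max_iter: int | None = None,
) -> VerificationReport:
    """Simulate one scenario and score its expectations.

    ``semantics`` selects which simulated summary is compared:
    ``"first"`` (first nonzero response, default) or ``"fixed"`` (the
    fixed point).  Raises ``ValueError`` when the scenario carries no
    expectations.
    """
    if semantics not in ("first", "fixed"):
        raise ValueError(f"semantics must be 'first' or 'fixed', got {semantics!r}")
    if not scenario.expected_outcomes:
        raise ValueError(f"scenario {scenario.name!r} has no expected outcomes")

    missing_act = sorted(el for el in scenario.activations if el not in model)
    present = Scenario(
        name=scenario.name,
        activations={el: s for el, s in scenario.activations.items()
                     if el in model},
        expected_outcomes=dict(scenario.expected_outcomes),
        notes=scenario.notes,
    )
    result = propagate(model, present, max_iter=max_iter)
    simulated = (result.first_response if semantics == "first"
                 else result.fixed_point)

    rows: list[ExpectationRow] = []
    absent: list[str] = []
    for el, expected in scenario.expected_outcomes.items():
        if el not in model:
            absent.append(el)
            continue
        sim = simulated[el]
        rows.append(ExpectationRow(el, expected, sim, sim == expected))

    agreement = (sum(r.match for r in rows) / len(rows)) if rows else None
    return VerificationReport(
        scenario=scenario.name,
        rows=rows,
        agreement=agreement,
        unmatched_expectations=absent,
        missing_activations=missing_act,
        result=result,
    )


def verify_suite(
    model: CLDModel,
    scenarios: Sequence[Scenario],
    semantics: str = "first",
    max_iter: int | None = None,
) -> VerificationSummary:
    """Verify every scenario; overall agreement is the mean over scenarios
    that had at least one scoreable expectation."""
    if not scenarios:
        raise ValueError("verify_suite needs at least one scenario")
    reports = [verify_scenario(model, sc, semantics=semantics, max_iter=max_iter)
               for sc in scenarios]
    scored = [r.agreement for r in reports if r.agreement is not None]
    overall = sum(scored) / len(scored) if scored else None
    return VerificationSummary(reports=reports, overall_agreement=overall)
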
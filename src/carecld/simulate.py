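"""Qualitative activation propagation on a signed causal loop diagram.

The simulator answers "what happens to the rest of the system when these
elements are pushed up or down?" at the sign level only.  Every connection
has equal weight; states live in {-1, 0, +1}.  Activated elements
(*sources*) are clamped to their activation sign.  All other elements are
updated synchronously: the raw input of ``v`` is the polarity-weighted sum
of its parents' current states, and its next state is the sign of that
sum.  Opposing influences of equal strength therefore cancel to 0
("unmodulated"), which is exactly the behaviour an equal-weight scheme
must show where a real system has a nonlinear interaction — the
demand–control U-shape being the canonical example: demand and control
push work overload and underload in exactly opposite ways, so any
activation confined to those two drivers leaves distress at 0.

Two summaries are reported per element:

``first_response``
    The first nonzero state the element ever attains (0 if it never
    leaves 0).  This is the *shock* semantics: the initial directional
    response before balancing feedback catches up, and the quantity
    intervention narratives describe ("activating X led to a reduction
    in Y").
``fixed_point``
    The converged state, or — when the synchronous dynamics settle into a
    state cycle instead of a fixed point — 0 for the elements whose state
    varies over the cycle (flagged ``ambiguous``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .model import CLDModel

SIGNS = (-1, 1)
STATUS_VALUES = ("source", "changed", "unchanged", "ambiguous", "unreached")


class UnknownElementError(KeyError):
    """A scenario references elements absent from the model."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(
            "scenario references unknown element(s): " + ", ".join(self.missing))


@dataclass
class Scenario:
    """An intervention: elements pushed up/down plus optional expectations.

    ``activations`` maps element ids to an initial sign in {-1, +1};
    ``expected_outcomes`` maps element ids to the signed outcome in
    {-1, 0, +1} the intervention is expected to produce, for use by the
    verification harness.
    """

    name: str
    activations: dict[str, int]
    expected_outcomes: dict[str, int] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        for el, sign in self.activations.items():
            if sign not in (-1, 1):
                raise ValueError(
                    f"activation sign for {el!r} must be -1 or +1, got {sign!r}")
        for el, sign in self.expected_outcomes.items():
            if sign not in (-1, 0, 1):
                raise ValueError(
                    f"expected outcome for {el!r} must be in {{-1,0,+1}}, "
                    f"got {sign!r}")

    def validate_against(self, model: CLDModel) -> None:
        missing = [el for el in self.activations if el not in model]
        if missing:
            raise UnknownElementError(missing)

    # -- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {"name": self.name, "activations": dict(self.activations)}
        if self.expected_outcomes:
            doc["expected_outcomes"] = dict(self.expected_outcomes)
        if self.notes:
            doc["notes"] = self.notes
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Scenario":
        return cls(
            name=doc["name"],
            activations={k: int(v) for k, v in (doc.get("activations") or {}).items()},
            expected_outcomes={
                k: int(v) for k, v in (doc.get("expected_outcomes") or {}).items()},
            notes=doc.get("notes", ""),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, allow_unicode=True),
            encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_scenarios(directory: str | Path) -> list[Scenario]:
    """Load every ``*.yaml``/``*.yml`` scenario in a directory, sorted by file name."""
    directory = Path(directory)
    paths = sorted(list(directory.glob("*.yaml")) + list(directory.glob("*.yml")))
    return [Scenario.from_yaml(p) for p in paths]


@dataclass
class SimulationResult:
    """Per-element qualitative outcomes of one propagation run."""

    scenario: str
    elements: tuple[str, ...]
    first_response: dict[str, int]
    fixed_point: dict[str, int]
    status: dict[str, str]
    converged: bool
    iterations: int
    trajectory: np.ndarray | None = None

    def to_frame(self, model: CLDModel | None = None) -> pd.DataFrame:
        """Tidy table, one row per element (stable element order)."""
        rows = []
        for el in self.elements:
            rows.append({
                "element": el,
                "category": model.elements[el].category if model else "",
                "first_response": self.first_response[el],
                "fixed_point": self.fixed_point[el],
                "status": self.status[el],
            })
        return pd.DataFrame(rows)


def _reachable_from(model: CLDModel, sources: Iterable[str]) -> set[str]:
    g = model.to_digraph()
    reached: set[str] = set()
    for s in sources:
        reached.add(s)
        reached |= nx.descendants(g, s)
    return reached


def propagate(
    model: CLDModel,
    scenario: Scenario,
    max_iter: int | None = None,
    record_trajectory: bool = False,
) -> SimulationResult:
    """Run clamped-source synchronous sign propagation.

    ``max_iter`` defaults to ``2 * n_elements``.  Non-convergence is not
    an error: if the trajectory re-enters a previously seen state the
    periodic orbit is identified and elements whose state varies over it
    are flagged ``ambiguous`` (fixed point reported as 0).
    """
    scenario.validate_against(model)
    if max_iter is None:
        max_iter = max(1, 2 * model.n_elements)
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")

    ids = list(model.element_ids)
    index = {el: i for i, el in enumerate(ids)}
    n = len(ids)

    adj = np.zeros((n, n), dtype=np.int64)
    for c in model.connections:
        adj[index[c.source], index[c.target]] = c.polarity

    source_idx = np.array(sorted(index[el] for el in scenario.activations),
                          dtype=np.intp)
    source_vals = np.array(
        [scenario.activations[ids[i]] for i in source_idx], dtype=np.int64)
    is_source = np.zeros(n, dtype=bool)
    is_source[source_idx] = True

    state = np.zeros(n, dtype=np.int64)
    state[source_idx] = source_vals
    first = state.copy()

    states = [state.copy()]
    seen: dict[bytes, int] = {state.tobytes(): 0}
    converged = False
    cycle_start: int | None = None
    iterations = 0

    for t in range(1, max_iter + 1):
        raw = state @ adj
        nxt = np.sign(raw)
        nxt[source_idx] = source_vals
        newly = (first == 0) & (nxt != 0)
        first[newly] = nxt[newly]
        iterations = t
        if np.array_equal(nxt, state):
            converged = True
            state = nxt
            states.append(state.copy())
            break
        state = nxt
        states.append(state.copy())
        key = state.tobytes()
        if key in seen:
            cycle_start = seen[key]
            break
        seen[key] = t

    ambiguous = np.zeros(n, dtype=bool)
    if converged:
        fixed = state.copy()
    elif cycle_start is not None:
        orbit = np.array(states[cycle_start:])
        ambiguous = (orbit != orbit[0]).any(axis=0)
        fixed = np.where(ambiguous, 0, orbit[0])
    else:
        # max_iter exhausted without closure: treat elements still moving
        # between the last two states as unresolved.
        ambiguous = states[-1] != states[-2]
        fixed = np.where(ambiguous, 0, states[-1])

    reached = _reachable_from(model, scenario.activations)
    status: dict[str, str] = {}
    for i, el in enumerate(ids):
        if is_source[i]:
            status[el] = "source"
        elif el not in reached:
            status[el] = "unreached"
        elif ambiguous[i]:
            status[el] = "ambiguous"
        elif first[i] != 0:
            status[el] = "changed"
        else:
            status[el] = "unchanged"

    return SimulationResult(
        scenario=scenario.name,
        elements=tuple(ids),
        first_response={el: int(first[i]) for i, el in enumerate(ids)},
        fixed_point={el: int(fixed[i]) for i, el in enumerate(ids)},
        status=status,
        converged=converged,
        iterations=iterations,
        trajectory=np.array(states) if record_trajectory else None,
    )


def run_scenario_suite(
    model: CLDModel,
    scenarios: Sequence[Scenario],
    max_iter: int | None = None,
) -> list[SimulationResult]:
    """Propagate each scenario in order; a pure function of its inputs."""
    return [propagate(model, sc, max_iter=max_iter) for sc in scenarios]


def path_sum_totals(
    model: CLDModel,
    scenario: Scenario,
    max_path_length: int | None = None,
    max_paths: int = 1_000_000,
) -> dict[str, int]:
    """Raw signed path sums behind :func:`path_sum_oracle`.

    For each element: the sum, over all simple directed paths from any
    activated source, of (activation × product of edge polarities along
    the path).  Paths never pass *through* another source, because
    clamped sources do not transmit upstream signals.  Sources report
    their own activation.

    Requires an acyclic model unless ``max_path_length`` bounds the
    enumeration; raises ``RuntimeError`` once ``max_paths`` simple paths
    have been expanded.
    """
    scenario.validate_against(model)
    g = model.to_digraph()
    if max_path_length is None:
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(
                "model contains cycles; pass a finite max_path_length")
        max_path_length = model.n_elements

    totals = {el: 0 for el in model.element_ids}
    sources = set(scenario.activations)
    counter = {"paths": 0}

    def dfs(node: str, sign: int, depth: int, visited: set[str]) -> None:
        counter["paths"] += 1
        if counter["paths"] > max_paths:
            raise RuntimeError(
                f"path enumeration exceeded the cap of {max_paths} paths")
        if depth >= max_path_length:
            return
        for _, nbr, data in g.out_edges(node, data=True):
            if nbr in visited or nbr in sources:
                continue
            path_sign = sign * data["polarity"]
            totals[nbr] += path_sign
            visited.add(nbr)
            dfs(nbr, path_sign, depth + 1, visited)
            visited.remove(nbr)

    for src, activation in scenario.activations.items():
        dfs(src, activation, 0, {src})

    for src, activation in scenario.activations.items():
        totals[src] = activation
    return totals


def path_sum_oracle(
    model: CLDModel,
    scenario: Scenario,
    max_path_length: int | None = None,
    max_paths: int = 1_000_000,
) -> dict[str, int]:
    """Independent sign oracle: sign of the exhaustive simple-path sum.

    See :func:`path_sum_totals` for the enumeration rules.  On models
    without multi-path aggregation (e.g. trees) this equals the
    propagation first response exactly; where paths of different lengths
    or multiplicities conflict, the two summaries can legitimately differ
    because propagation flattens states to signs at every step.
    """
    totals = path_sum_totals(model, scenario,
                             max_path_length=max_path_length,
                             max_paths=max_paths)
    result = {el: int(np.sign(total)) for el, total in totals.items()}
    for src, activation in scenario.activations.items():
        result[src] = activation
    return result
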
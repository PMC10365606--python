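"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own algorithms: cycle
enumeration is a plain DFS over adjacency dicts, and path-sum signs are
computed by naive recursive path enumeration, so that the package's
networkx-backed implementations are checked against genuinely independent
code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from carecld import (
    CLDModel,
    ElementNode,
    Scenario,
    SignedConnection,
    build_homecare_fixture,
    build_stress_core,
    fixture_scenarios,
)


@pytest.fixture(scope="session")
def fixture_model() -> CLDModel:
    return build_homecare_fixture()


@pytest.fixture(scope="session")
def stress_core() -> CLDModel:
    return build_stress_core()


@pytest.fixture(scope="session")
def scenarios() -> list[Scenario]:
    return fixture_scenarios()


# ---------------------------------------------------------------------------
# model builders


def make_model(edges, n_nodes=None, name="test") -> CLDModel:
    """Build a model from (source, target, polarity) triples.

    Node ids are collected from the edges; pass ``n_nodes`` to add
    ``x00..x{n-1}`` regardless (so isolated nodes can exist).
    """
    ids = []
    if n_nodes is not None:
        ids = [f"x{i:02d}" for i in range(n_nodes)]
    for s, t, _ in edges:
        for e in (s, t):
            if e not in ids:
                ids.append(e)
    elements = [ElementNode(e, e, "stress") for e in ids]
    connections = [SignedConnection(s, t, p) for s, t, p in edges]
    return CLDModel(elements, connections, name=name)


def random_signed_digraph(rng: np.random.Generator, n: int, p: float = 0.3,
                          neg: float = 0.3) -> CLDModel:
    """Erdős–Rényi signed digraph (cycles allowed, no self-loops)."""
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                sign = -1 if rng.random() < neg else 1
                edges.append((f"x{i:02d}", f"x{j:02d}", sign))
    return make_model(edges, n_nodes=n)


def random_signed_dag(rng: np.random.Generator, n: int, p: float = 0.25,
                      neg: float = 0.25) -> CLDModel:
    """Random DAG: edges respect a random topological order."""
    order = rng.permutation(n)
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                sign = -1 if rng.random() < neg else 1
                edges.append((f"x{order[a]:02d}", f"x{order[b]:02d}", sign))
    return make_model(edges, n_nodes=n)


def random_signed_tree(rng: np.random.Generator, n: int,
                       neg: float = 0.25) -> CLDModel:
    """Random out-tree rooted at x00: every element has a unique path
    from the root, so path-sum and propagation semantics coincide."""
    edges = []
    for child in range(1, n):
        parent = int(rng.integers(child))
        sign = -1 if rng.random() < neg else 1
        edges.append((f"x{parent:02d}", f"x{child:02d}", sign))
    return make_model(edges, n_nodes=n)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_cycles(model: CLDModel) -> set[tuple[tuple[str, ...], str]]:
    """All simple directed cycles with polarity, by plain DFS.

    Each cycle is reported once, rotated so its smallest element comes
    first; polarity is 'reinforcing'/'balancing' from the sign product.
    """
    adj: dict[str, list[tuple[str, int]]] = {el: [] for el in model.element_ids}
    for c in model.connections:
        adj[c.source].append((c.target, c.polarity))
    ordered = sorted(model.element_ids)
    found: set[tuple[tuple[str, ...], str]] = set()

    def dfs(start: str, node: str, path: list[str], sign: int) -> None:
        for nbr, pol in adj[node]:
            if nbr == start:
                polarity = "reinforcing" if sign * pol > 0 else "balancing"
                found.add((tuple(path), polarity))
            elif nbr > start and nbr not in path:
                path.append(nbr)
                dfs(start, nbr, path, sign * pol)
                path.pop()

    for start in ordered:
        dfs(start, start, [start], 1)
    return found


def brute_force_path_sums(model: CLDModel, activations: dict[str, int]
                          ) -> dict[str, int]:
    """Naive recursive path-sum totals (paths never cross a source)."""
    adj: dict[str, list[tuple[str, int]]] = {el: [] for el in model.element_ids}
    for c in model.connections:
        adj[c.source].append((c.target, c.polarity))
    totals = {el: 0 for el in model.element_ids}

    def dfs(node: str, sign: int, visited: set[str]) -> None:
        for nbr, pol in adj[node]:
            if nbr in visited or nbr in activations:
                continue
            totals[nbr] += sign * pol
            dfs(nbr, sign * pol, visited | {nbr})

    for src, act in activations.items():
        dfs(src, act, {src})
    for src, act in activations.items():
        totals[src] = act
    return totals


def brute_force_path_signs(model: CLDModel, activations: dict[str, int]
                           ) -> dict[str, int]:
    sums = brute_force_path_sums(model, activations)
    return {el: int(math.copysign(1, v)) if v else 0 for el, v in sums.items()}
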
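"""Seeded generator of synthetic CLD models.

The generator emulates the statistical shape of the full published
home-care model — 122 elements split over the six categories (stress 6,
home care staff 44, home care user 28, organization 26, social support
13, societal 5) joined by 223 signed connections, i.e. a sparse signed
digraph with feedback cycles and a minority of negative edges — without
any of its domain structure.  It exists so that loop analysis, simulation
and metrics can be exercised and property-tested at full published scale
with reproducible, seed-determined inputs.

Edge placement is uniform over allowed ordered pairs (no self-loops, no
duplicate pairs); a configurable number of short cycles is planted first,
alternating reinforcing and balancing polarity, so cycle-dependent code
always has work to do.  The negative-edge fraction defaults to 0.25 — a
package choice, since the published model's negative-edge count is not
stated in its narrative — and is adjusted to guarantee at least one
negative edge whenever the fraction is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CATEGORIES, CLDModel, ElementNode, SignedConnection, assert_valid

#: Category sizes of the full published model.
DEFAULT_CATEGORY_SIZES: dict[str, int] = {
    "stress": 6,
    "home_care_staff": 44,
    "home_care_user": 28,
    "organization": 26,
    "social_support": 13,
    "societal": 5,
}
DEFAULT_N_CONNECTIONS = 223
DEFAULT_NEGATIVE_FRACTION = 0.25
DEFAULT_ENSURE_CYCLES = 3


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic model draw."""

    category_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SIZES))
    n_connections: int = DEFAULT_N_CONNECTIONS
    negative_fraction: float = DEFAULT_NEGATIVE_FRACTION
    ensure_cycles: int = DEFAULT_ENSURE_CYCLES
    seed: int = 0

    @property
    def n_elements(self) -> int:
        return sum(self.category_sizes.values())

    def validate(self) -> None:
        for cat, size in self.category_sizes.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if size < 0:
                raise ValueError(f"category size for {cat!r} must be >= 0")
        n = self.n_elements
        if self.n_connections < 0:
            raise ValueError("n_connections must be >= 0")
        if self.n_connections > n * (n - 1):
            raise ValueError(
                f"{self.n_connections} connections do not fit in a simple "
                f"digraph on {n} elements")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must lie in [0, 1]")
        if self.ensure_cycles < 0:
            raise ValueError("ensure_cycles must be >= 0")


def _pair_from_index(k: int, n: int) -> tuple[int, int]:
    """Bijection from [0, n(n-1)) onto ordered pairs skipping the diagonal."""
    i, r = divmod(k, n - 1)
    j = r if r < i else r + 1
    return i, j


def generate_cld(spec: SyntheticSpec) -> CLDModel:
    """Draw one synthetic model; identical spec (incl. seed) → identical model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_elements

    elements: list[ElementNode] = []
    for cat in CATEGORIES:
        for i in range(spec.category_sizes.get(cat, 0)):
            eid = f"{cat}_{i + 1:03d}"
            elements.append(ElementNode(
                id=eid,
                label=f"{cat.replace('_', ' ')} element {i + 1}",
                category=cat,
            ))
    ids = [el.id for el in elements]

    used_pairs: set[tuple[int, int]] = set()
    edges: list[tuple[int, int, int]] = []  # (src, tgt, polarity)

    def polarity_draw() -> int:
        return -1 if rng.random() < spec.negative_fraction else 1

    # Plant short cycles (alternating reinforcing/balancing) while the
    # edge budget allows.
    planted = 0
    attempts = 0
    while planted < spec.ensure_cycles and attempts < 50 * max(1, spec.ensure_cycles):
        attempts += 1
        length = int(rng.integers(2, 5))
        if n < length or len(edges) + length > spec.n_connections:
            break
        nodes = rng.choice(n, size=length, replace=False)
        pairs = [(int(nodes[i]), int(nodes[(i + 1) % length]))
                 for i in range(length)]
        if any(p in used_pairs for p in pairs):
            continue
        signs = [polarity_draw() for _ in pairs]
        want_reinforcing = planted % 2 == 0
        product = int(np.prod(signs))
        if (product > 0) != want_reinforcing:
            signs[-1] = -signs[-1]
        for (src, tgt), sign in zip(pairs, signs):
            used_pairs.add((src, tgt))
            edges.append((src, tgt, sign))
        planted += 1

    # Fill the remaining budget uniformly over unused ordered pairs.
    remaining = spec.n_connections - len(edges)
    total_pairs = n * (n - 1)
    while remaining > 0:
        draw = rng.choice(total_pairs, size=min(total_pairs, 2 * remaining),
                          replace=False)
        for k in draw:
            pair = _pair_from_index(int(k), n)
            if pair in used_pairs:
                continue
            used_pairs.add(pair)
            edges.append((pair[0], pair[1], polarity_draw()))
            remaining -= 1
            if remaining == 0:
                break

    # Guarantee at least one negative edge when the fraction asks for any.
    if spec.negative_fraction > 0 and edges and all(e[2] > 0 for e in edges):
        k = int(rng.integers(len(edges)))
        src, tgt, _ = edges[k]
        edges[k] = (src, tgt, -1)

    connections = [SignedConnection(ids[s], ids[t], p) for s, t, p in edges]
    return assert_valid(CLDModel(
        elements, connections, name=f"synthetic_seed{spec.seed}",
        metadata={"generator": "carecld.synthetic", "seed": str(spec.seed)},
    ))


def perturb_model(
    model: CLDModel,
    n_sign_flips: int,
    n_edge_rewires: int,
    seed: int,
) -> CLDModel:
    """Seeded structural perturbation for robustness testing.

    Flips the polarity of ``n_sign_flips`` uniformly chosen connections,
    then rewires the target of ``n_edge_rewires`` uniformly chosen
    connections (the source endpoint is preserved; new targets avoid
    self-loops and duplicate pairs).  Raises ``ValueError`` when the
    requested counts are infeasible.
    """
    rng = np.random.default_rng(seed)
    connections = list(model.connections)
    m = len(connections)
    if n_sign_flips < 0 or n_sign_flips > m:
        raise ValueError(f"cannot flip {n_sign_flips} of {m} connections")
    if n_edge_rewires < 0 or n_edge_rewires > m:
        raise ValueError(f"cannot rewire {n_edge_rewires} of {m} connections")

    ids = list(model.element_ids)
    if n_sign_flips:
        for k in rng.choice(m, size=n_sign_flips, replace=False):
            c = connections[int(k)]
            connections[int(k)] = SignedConnection(
                c.source, c.target, -c.polarity, c.evidence_refs)

    if n_edge_rewires:
        for k in rng.choice(m, size=n_edge_rewires, replace=False):
            k = int(k)
            c = connections[k]
            taken = {(cc.source, cc.target) for i, cc in enumerate(connections)
                     if i != k}
            candidates = [t for t in ids
                          if t != c.source and (c.source, t) not in taken]
            if not candidates:
                raise ValueError(
                    f"no feasible rewiring target for connection "
                    f"{c.source}->{c.target}")
            new_target = candidates[int(rng.integers(len(candidates)))]
            connections[k] = SignedConnection(
                c.source, new_target, c.polarity, c.evidence_refs)

    return assert_valid(CLDModel(
        list(model), connections, name=f"{model.name}_perturbed",
        metadata=dict(model.metadata)))
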
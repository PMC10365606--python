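"""Feedback-loop enumeration and polarity classification.

A feedback loop is a simple directed cycle of a CLD.  Its polarity is the
product of the edge polarities along the cycle: positive products give
*reinforcing* loops (change around the loop amplifies itself; candidate
leverage points for policy), negative products give *balancing* loops
(the loop counteracts change).  Cycles are reported in canonical rotation
(lexicographically smallest element first) and sorted by (length,
elements) so output is stable and diffable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import CLDModel, SignedConnection

logger = logging.getLogger(__name__)

REINFORCING = "reinforcing"
BALANCING = "balancing"

#: Stop enumerating (with a warning) once this many cycles have been found.
DEFAULT_MAX_CYCLES = 1_000_000


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle with its derived polarity."""

    elements: tuple[str, ...]
    polarity: str
    length: int

    def __post_init__(self) -> None:
        if self.length != len(self.elements):
            raise ValueError("length must equal the number of elements")

    def edges(self) -> list[tuple[str, str]]:
        els = self.elements
        return [(els[i], els[(i + 1) % len(els)]) for i in range(len(els))]


def _canonical(cycle: Sequence[str]) -> tuple[str, ...]:
    """Rotate so the lexicographically smallest element comes first."""
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[k:]) + tuple(cycle[:k])


def loop_sign(polarities: Iterable[int]) -> int:
    return math.prod(polarities)


def classify_loop(loop_edges: Sequence[SignedConnection | int]) -> str:
    """Classify a cycle from its edges (or bare polarities).

    Returns ``"reinforcing"`` when the product of signs is +1, otherwise
    ``"balancing"``.
    """
    signs = [e if isinstance(e, int) else e.polarity for e in loop_edges]
    if not signs:
        raise ValueError("a loop needs at least one edge")
    return REINFORCING if loop_sign(signs) > 0 else BALANCING


def enumerate_loops(
    model: CLDModel,
    max_length: int | None = None,
    max_cycles: int = DEFAULT_MAX_CYCLES,
) -> list[FeedbackLoop]:
    """All simple directed cycles of ``model`` (optionally length-capped).

    Each cycle appears exactly once, in canonical rotation.  If more than
    ``max_cycles`` cycles exist a warning is logged and enumeration stops
    at the cap.
    """
    if max_length is not None and max_length < 2:
        raise ValueError("max_length must be >= 2 (self-loops are rejected)")
    g = model.to_digraph()
    polarity = {(c.source, c.target): c.polarity for c in model.connections}

    loops: list[FeedbackLoop] = []
    for cycle in nx.simple_cycles(g, length_bound=max_length):
        els = _canonical(cycle)
        signs = [polarity[e] for e in
                 ((els[i], els[(i + 1) % len(els)]) for i in range(len(els)))]
        loops.append(FeedbackLoop(
            elements=els, polarity=classify_loop(signs), length=len(els)))
        if len(loops) >= max_cycles:
            logger.warning(
                "cycle enumeration stopped at the cap of %d cycles", max_cycles)
            break
    loops.sort(key=lambda lp: (lp.length, lp.elements))
    return loops


def loop_participation(
    model: CLDModel,
    max_length: int | None = None,
    loops: Sequence[FeedbackLoop] | None = None,
) -> pd.DataFrame:
    """Per-element loop membership counts (leverage-point screening).

    Returns a table with columns ``element``, ``reinforcing``,
    ``balancing``, ``total``, covering every element (zeros included),
    sorted by total descending then element id.  Pass ``loops`` to reuse
    an existing enumeration.
    """
    if loops is None:
        loops = enumerate_loops(model, max_length=max_length)
    counts = {el: {"reinforcing": 0, "balancing": 0} for el in model.element_ids}
    for lp in loops:
        for el in lp.elements:
            counts[el][lp.polarity] += 1
    table = pd.DataFrame(
        [
            {"element": el,
             "reinforcing": c["reinforcing"],
             "balancing": c["balancing"],
             "total": c["reinforcing"] + c["balancing"]}
            for el, c in counts.items()
        ]
    )
    return (table.sort_values(["total", "element"], ascending=[False, True])
            .reset_index(drop=True))
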
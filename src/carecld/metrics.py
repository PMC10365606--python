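"""Structural (social-network-analysis) characterization of a CLD.

Signs are ignored throughout: the metrics describe the wiring of the
underlying directed graph.  The table combines the standard centrality
quartet (in/out degree, betweenness on shortest directed paths, outward
closeness, eigenvector centrality on the undirected underlying graph)
with ``downstream_reach``, the number of elements an element can
influence through directed paths — the quantity that matters most for
screening intervention targets.

``rank_leverage`` orders elements by a documented composite:
participation in reinforcing loops first (reinforcing loops amplify
change, making their members prime leverage points), then total loop
participation, then downstream reach; ties break on element id.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .loops import enumerate_loops, loop_participation
from .model import CLDModel

CENTRALITY_COLUMNS = (
    "in_degree", "out_degree", "betweenness", "closeness",
    "eigenvector", "downstream_reach",
)


def compute_centralities(model: CLDModel) -> pd.DataFrame:
    """Per-element structural metrics, indexed by element id.

    Betweenness is unnormalized pair counting on shortest directed paths;
    closeness is outward (how quickly an element reaches the rest of the
    graph); eigenvector centrality is computed on the undirected
    underlying graph so it is well defined on acyclic models too.
    """
    g = model.to_digraph()
    ids = list(model.element_ids)
    if not ids:
        return pd.DataFrame(columns=list(CENTRALITY_COLUMNS))

    betweenness = nx.betweenness_centrality(g, normalized=False)
    # closeness_centrality measures inward distance; reverse for outward.
    closeness = nx.closeness_centrality(g.reverse(copy=False))
    undirected = g.to_undirected()
    if undirected.number_of_edges() > 0:
        eigenvector = nx.eigenvector_centrality(undirected, max_iter=1000)
        # power iteration leaves numerical dust on degree-0 nodes whose
        # exact centrality is 0
        for el in ids:
            if undirected.degree(el) == 0:
                eigenvector[el] = 0.0
    else:
        eigenvector = {el: 0.0 for el in ids}

    rows = {
        el: {
            "in_degree": g.in_degree(el),
            "out_degree": g.out_degree(el),
            "betweenness": betweenness[el],
            "closeness": closeness[el],
            "eigenvector": eigenvector[el],
            "downstream_reach": len(nx.descendants(g, el)),
        }
        for el in ids
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "element"
    return table.loc[ids, list(CENTRALITY_COLUMNS)]


def rank_leverage(model: CLDModel, max_length: int | None = None) -> list[str]:
    """Elements ordered from highest to lowest leverage.

    Sort key (descending, lexicographic): reinforcing-loop participation,
    total loop participation, downstream reach; ties broken by element id
    (ascending).
    """
    if model.n_elements == 0:
        return []
    loops = enumerate_loops(model, max_length=max_length)
    participation = loop_participation(model, loops=loops).set_index("element")
    g = model.to_digraph()
    reach = {el: len(nx.descendants(g, el)) for el in model.element_ids}
    return sorted(
        model.element_ids,
        key=lambda el: (
            -participation.loc[el, "reinforcing"],
            -participation.loc[el, "total"],
            -reach[el],
            el,
        ),
    )
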
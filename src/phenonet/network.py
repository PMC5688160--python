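"""Effect-size network construction, giant component, and Kruskal MST.

Significant pairs become edges of an undirected graph whose weights are the
effect size R² and the effect-size distance d = (1−R²)/R², so strongly
associated variables sit close together. The minimum spanning tree under d
then keeps, greedily, the strongest associations that connect everything.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .effects import PairResult, significant_pairs

log = logging.getLogger(__name__)


class DisconnectedNetworkError(ValueError):
    """Raised when an MST is requested for a disconnected network."""


def distance_transform(r_squared: float) -> float:
    """Effect-size distance d = (1−R²)/R², strictly decreasing in R²."""
    if r_squared <= 0.0 or r_squared > 1.0:
        raise ValueError(f"effect size must be in (0, 1], got {r_squared}")
    return (1.0 - r_squared) / r_squared


def build_network(
    pairs: Sequence[PairResult],
    alpha_eff: float,
    nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Build the thresholded effect-size network.

    An edge appears iff its pair has status ``ok``, p ≤ α_eff, and R² > 0
    (a zero effect would map to infinite distance and is dropped instead).
    Nodes from ``nodes`` (default: every variable appearing in ``pairs``)
    are retained even when isolated.
    """
    if not 0.0 < alpha_eff < 1.0:
        raise ValueError("alpha_eff must be in (0, 1)")
    g = nx.Graph()
    if nodes is None:
        node_set = sorted({p.var_a for p in pairs} | {p.var_b for p in pairs})
    else:
        node_set = sorted(nodes)
    g.add_nodes_from(node_set)
    # insertion in canonical (var_a, var_b) order makes downstream stable
    # sorts (Kruskal ties) deterministic
    for pr in sorted(significant_pairs(pairs, alpha_eff), key=lambda p: (p.var_a, p.var_b)):
        if pr.effect_size is None or pr.effect_size <= 0.0:
            continue
        g.add_edge(
            pr.var_a, pr.var_b,
            effect_size=float(pr.effect_size),
            distance=distance_transform(pr.effect_size),
        )
    return g


def giant_component(net: nx.Graph) -> tuple[nx.Graph, list[str]]:
    """The largest connected component and the excluded (isolated) nodes.

    Size ties are broken in favour of the component containing the
    lexicographically smallest node name. An empty network yields an empty
    graph.
    """
    if net.number_of_nodes() == 0:
        return net.copy(), []
    comps = list(nx.connected_components(net))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    excluded = sorted(set(net.nodes) - best)
    return net.subgraph(best).copy(), excluded


def kruskal_mst(net: nx.Graph) -> nx.Graph:
    """Minimum spanning tree under the effect-size distance, via Kruskal.

    Ties in d are broken by the canonical edge name order (var_a, var_b),
    which edge-insertion order plus the algorithm's stable sort guarantees.
    """
    if net.number_of_nodes() == 0:
        return net.copy()
    if not nx.is_connected(net):
        raise DisconnectedNetworkError(
            "network is disconnected; extract the giant component first"
        )
    rebuilt = nx.Graph()
    rebuilt.add_nodes_from(sorted(net.nodes))
    for u, v in sorted(tuple(sorted(e)) for e in net.edges):
        rebuilt.add_edge(u, v, **net.edges[u, v])
    return nx.minimum_spanning_tree(rebuilt, weight="distance", algorithm="kruskal")


def edges_frame(net: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (var_a, var_b, effect_size, distance)."""
    rows = [
        (min(u, v), max(u, v), d.get("effect_size"), d.get("distance"))
        for u, v, d in net.edges(data=True)
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["var_a", "var_b", "effect_size", "distance"])


def write_network(net: nx.Graph, basename: str | Path) -> None:
    """Write a network as GraphML + GEXF (Gephi-ready) + TSV edge list."""
    base = Path(basename)
    nx.write_graphml(net, base.with_suffix(".graphml"))
    nx.write_gexf(net, base.with_suffix(".gexf"))
    edges_frame(net).to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
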
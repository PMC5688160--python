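"""Louvain clustering, induced cluster networks, and centrality classes.

Clustering maximizes weighted Newman modularity with the effect size R²
as the edge weight (closeness, not distance). Contracting each cluster to
a node gives the induced cluster network; normalized betweenness
centrality under the distance weight then splits clusters into central
(BC ≥ 0.5), noncentral, and — among the noncentral — peripheral (BC = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

log = logging.getLogger(__name__)

CENTRAL = "central"
NONCENTRAL = "noncentral"
PERIPHERAL = "peripheral"

DEFAULT_CENTRALITY_CUTOFF = 0.5


@dataclass
class ClusterAssignment:
    """Node → cluster-id map with the partition's modularity.

    Cluster ids are consecutive integers from 1, ordered by decreasing
    cluster size (ties by smallest member name) so output is reproducible.
    """

    labels: dict[str, int]
    modularity: float
    source: str = "full"  # "full" | "mst"
    seed: int = 0

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.labels.items():
            out.setdefault(cid, set()).add(node)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def modularity(net: nx.Graph, labels: Mapping[str, int], weight: str = "effect_size") -> float:
    """Weighted Newman modularity Q ∈ [−0.5, 1] of a full node labeling."""
    missing = [n for n in net.nodes if n not in labels]
    if missing:
        raise ValueError(f"unlabeled nodes: {missing[:5]}")
    if net.number_of_edges() == 0:
        return 0.0
    comms: dict[int, set[str]] = {}
    for node in net.nodes:
        comms.setdefault(labels[node], set()).add(node)
    return float(nx.community.modularity(net, comms.values(), weight=weight))


def louvain_partition(
    net: nx.Graph,
    seed: int = 0,
    source: str = "full",
    weight: str = "effect_size",
    resolution: float = 1.0,
) -> ClusterAssignment:
    """Louvain community detection with R² weights, deterministic per seed."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    if net.number_of_edges() == 0:
        comms = [{n} for n in sorted(net.nodes)]
    else:
        comms = nx.community.louvain_communities(
            net, weight=weight, resolution=resolution, seed=seed
        )
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = {node: cid for cid, comm in enumerate(ordered, start=1) for node in comm}
    q = modularity(net, labels, weight=weight) if net.number_of_edges() else 0.0
    return ClusterAssignment(labels=labels, modularity=q, source=source, seed=seed)


def induce_cluster_network(parent: nx.Graph, assignment: ClusterAssignment) -> nx.Graph:
    """Contract each cluster of a spanning tree to a single node.

    Nodes are cluster ids with a ``size`` attribute; an edge joins two
    clusters adjacent in the parent, weighted by the parent edge's
    distance (and its effect size). Should several parent edges join the
    same cluster pair — possible when a cluster is not connected inside
    the parent tree — the minimum distance wins and a warning is logged,
    since a tree contraction normally yields exactly one linking edge.
    """
    missing = [n for n in parent.nodes if n not in assignment.labels]
    if missing:
        raise ValueError(f"assignment does not cover parent nodes: {missing[:5]}")
    induced = nx.Graph()
    for cid, members in sorted(assignment.clusters().items()):
        induced.add_node(cid, size=len(members))
    for u, v, data in parent.edges(data=True):
        cu, cv = assignment.labels[u], assignment.labels[v]
        if cu == cv:
            continue
        d = float(data["distance"])
        if induced.has_edge(cu, cv):
            log.warning(
                "multiple parent edges between clusters %s and %s; keeping min distance",
                cu, cv,
            )
            if d >= induced.edges[cu, cv]["distance"]:
                continue
        induced.add_edge(cu, cv, distance=d,
                         effect_size=float(data.get("effect_size", 1.0 / (1.0 + d))))
    return induced


def betweenness_scores(induced: nx.Graph) -> dict[int, float]:
    """Normalized betweenness centrality under distance-weighted shortest paths.

    Normalization divides by (n−1)(n−2)/2 pairs, so values lie in [0, 1];
    with fewer than 3 nodes every score is 0.
    """
    if induced.number_of_nodes() < 3:
        return {n: 0.0 for n in induced.nodes}
    return {
        n: float(bc)
        for n, bc in nx.betweenness_centrality(
            induced, weight="distance", normalized=True
        ).items()
    }


def classify_centrality(
    bc: Mapping[int, float], cutoff: float = DEFAULT_CENTRALITY_CUTOFF
) -> dict[int, str]:
    """central if BC ≥ cutoff; otherwise noncentral, or peripheral if BC = 0."""
    out = {}
    for node, score in bc.items():
        if score >= cutoff:
            out[node] = CENTRAL
        elif score == 0.0:
            out[node] = PERIPHERAL
        else:
            out[node] = NONCENTRAL
    return out


@dataclass
class InducedClusterNetwork:
    """Contracted cluster graph bundled with BC scores and centrality classes."""

    graph: nx.Graph
    bc: dict[int, float] = field(default_factory=dict)
    centrality_class: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_assignment(
        cls,
        parent: nx.Graph,
        assignment: ClusterAssignment,
        cutoff: float = DEFAULT_CENTRALITY_CUTOFF,
    ) -> "InducedClusterNetwork":
        g = induce_cluster_network(parent, assignment)
        bc = betweenness_scores(g)
        classes = classify_centrality(bc, cutoff=cutoff)
        for n in g.nodes:
            g.nodes[n]["betweenness"] = bc[n]
            g.nodes[n]["centrality_class"] = classes[n]
        return cls(graph=g, bc=bc, centrality_class=classes)
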
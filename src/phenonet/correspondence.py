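"""Correspondence between the MST-derived and full-network partitions.

Each MST cluster is matched to the full-network cluster at minimum Jaccard
distance; the subset similarity index j = J/J_max then measures how close
the matched pair is to a subset–superset relation, and adjusted mutual
information summarizes global agreement between the two labelings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score

from .community import ClusterAssignment

RELATION_IDENTICAL = "identical"
RELATION_SUBSET = "subset"
RELATION_SUPERSET = "superset"
RELATION_NEAR = "near"      # j >= 0.9
RELATION_CLOSE = "close"    # 0.8 <= j < 0.9
RELATION_OTHER = "other"


def jaccard_similarity(x: set, y: set) -> float:
    """J(X, Y) = |X∩Y| / |X∪Y| for non-empty finite sets."""
    if not x or not y:
        raise ValueError("sets must be non-empty")
    return len(x & y) / len(x | y)


def jaccard_max(x: set, y: set) -> float:
    """Largest attainable J given the two cardinalities: min|·|/max|·|."""
    if not x or not y:
        raise ValueError("sets must be non-empty")
    return min(len(x), len(y)) / max(len(x), len(y))


def subset_similarity(x: set, y: set) -> float:
    """j = J/J_max ∈ [0, 1]; equals 1 iff one set contains the other."""
    return jaccard_similarity(x, y) / jaccard_max(x, y)


def _relation(x: set, y: set, j_sub: float) -> str:
    if x == y:
        return RELATION_IDENTICAL
    if x < y:
        return RELATION_SUBSET
    if x > y:
        return RELATION_SUPERSET
    if j_sub >= 0.9:
        return RELATION_NEAR
    if j_sub >= 0.8:
        return RELATION_CLOSE
    return RELATION_OTHER


def adjusted_mutual_information(
    labels_a: Sequence, labels_b: Sequence, average_method: str = "arithmetic"
) -> float:
    """Chance-corrected agreement between two labelings of the same items.

    AMI = (MI − E[MI]) / (mean(H_a, H_b) − E[MI]) with the expectation taken
    under the permutation (hypergeometric) model; the entropy mean defaults
    to arithmetic.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must cover the same items")
    return float(
        adjusted_mutual_info_score(labels_a, labels_b, average_method=average_method)
    )


@dataclass
class CorrespondenceReport:
    """Per-MST-cluster matches plus the global AMI."""

    table: pd.DataFrame
    ami: float
    ami_average_method: str = "arithmetic"
    relation_counts: dict[str, int] = field(default_factory=dict)

    def write(self, tsv_path, json_path=None) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            import json

            summary = {
                "ami": self.ami,
                "ami_average_method": self.ami_average_method,
                "relation_counts": self.relation_counts,
                "n_mst_clusters": int(len(self.table)),
            }
            with open(json_path, "w") as fh:
                json.dump(summary, fh, indent=2)


def _best_match(x: set, candidates: Mapping[int, set]) -> int:
    """Full cluster minimizing D_J; ties → larger intersection, then smaller id."""
    best_id, best_key = None, None
    for cid in sorted(candidates):
        y = candidates[cid]
        dj = 1.0 - jaccard_similarity(x, y)
        key = (dj, -len(x & y), cid)
        if best_key is None or key < best_key:
            best_id, best_key = cid, key
    assert best_id is not None
    return best_id


def match_clusters(
    mst_assign: ClusterAssignment,
    full_assign: ClusterAssignment,
    average_method: str = "arithmetic",
) -> CorrespondenceReport:
    """Match every MST cluster to its closest full-network cluster.

    Closeness is minimum Jaccard distance D_J = 1 − J; each match carries
    J, J_max, the subset similarity j and a relation band (identical /
    subset / superset / near j ≥ 0.9 / close 0.8 ≤ j < 0.9 / other).
    """
    if set(mst_assign.labels) != set(full_assign.labels):
        raise ValueError("assignments must cover the same node set")
    mst_clusters = mst_assign.clusters()
    full_clusters = full_assign.clusters()

    rows = []
    for mid in sorted(mst_clusters):
        x = mst_clusters[mid]
        fid = _best_match(x, full_clusters)
        y = full_clusters[fid]
        jac = jaccard_similarity(x, y)
        jmax = jaccard_max(x, y)
        j_sub = jac / jmax
        rows.append(
            {
                "mst_cluster": mid,
                "matched_full_cluster": fid,
                "mst_size": len(x),
                "full_size": len(y),
                "J": jac,
                "D_J": 1.0 - jac,
                "J_max": jmax,
                "j": j_sub,
                "relation": _relation(x, y, j_sub),
            }
        )
    table = pd.DataFrame(rows)
    nodes = sorted(mst_assign.labels)
    ami = adjusted_mutual_information(
        [mst_assign.labels[n] for n in nodes],
        [full_assign.labels[n] for n in nodes],
        average_method=average_method,
    )
    counts = table["relation"].value_counts().to_dict()
    return CorrespondenceReport(
        table=table, ami=ami, ami_average_method=average_method,
        relation_counts={k: int(v) for k, v in counts.items()},
    )
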
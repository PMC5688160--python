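"""End-to-end pipeline: cohort → pairs → network → MST → clusters → report.

Stages run in a fixed order — pairwise effect sizes, Bonferroni threshold,
effect-size network, giant component, Kruskal MST, Louvain on both graphs,
induced cluster network with betweenness classification, and finally the
cluster-correspondence analysis. Every artifact is written to the output
directory together with a JSON manifest of counts, seeds and settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .cohort import CohortTable, read_cohort, write_cohort
from .community import (
    DEFAULT_CENTRALITY_CUTOFF,
    ClusterAssignment,
    InducedClusterNetwork,
    louvain_partition,
)
from .correspondence import CorrespondenceReport, adjusted_mutual_information, match_clusters
from .effects import DEFAULT_MIN_N, bonferroni_threshold, compute_all_pairs, write_pairs
from .network import build_network, giant_component, kruskal_mst, write_network
from .synthetic import GroundTruth, SyntheticSpec, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    Exactly one of (``cohort_path`` + ``metadata_path``) or ``synthetic``
    must be provided.
    """

    cohort_path: str | None = None
    metadata_path: str | None = None
    synthetic: SyntheticSpec | None = None
    alpha: float = 0.05
    min_n: int = DEFAULT_MIN_N
    louvain_seed: int = 0
    ami_average_method: str = "arithmetic"
    centrality_cutoff: float = DEFAULT_CENTRALITY_CUTOFF
    output_dir: str = "phenonet_out"

    def __post_init__(self) -> None:
        has_files = self.cohort_path is not None or self.metadata_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError("provide either input files or a synthetic spec, not both")
        if has_files and (self.cohort_path is None or self.metadata_path is None):
            raise ValueError("both cohort_path and metadata_path are required")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha outside (0, 1)")
        if self.min_n < 3:
            raise ValueError("min_n must be at least 3")
        if not 0.0 <= self.centrality_cutoff <= 1.0:
            raise ValueError("centrality_cutoff outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML file.

        A ``synthetic:`` mapping becomes a :class:`SyntheticSpec`
        (``block_sizes`` as a list); all other keys map 1:1 to fields.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "block_sizes" in syn:
                syn["block_sizes"] = tuple(syn["block_sizes"])
            raw["synthetic"] = SyntheticSpec(**syn)
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus the manifest."""

    table: CohortTable
    truth: GroundTruth | None
    pairs: list
    alpha_eff: float
    network: nx.Graph
    giant: nx.Graph
    isolated: list[str]
    mst: nx.Graph
    full_assign: ClusterAssignment
    mst_assign: ClusterAssignment
    induced: InducedClusterNetwork
    correspondence: CorrespondenceReport
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    payload = asdict(config)
    payload.pop("output_dir", None)  # hash identifies the analysis, not its destination
    if config.synthetic is not None:
        payload["synthetic"] = asdict(config.synthetic)
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage; optionally persist all artifacts to the output dir."""
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    truth: GroundTruth | None = None
    if config.synthetic is not None:
        table, truth = generate_cohort(config.synthetic)
        if write:
            write_cohort(table, outdir / "cohort.csv", outdir / "cohort_metadata.csv",
                         block_labels=truth.block_label)
    else:
        table = read_cohort(config.cohort_path, config.metadata_path)

    n_vars = len(table.variables)
    pairs = compute_all_pairs(table, min_n=config.min_n)
    alpha_eff = bonferroni_threshold(config.alpha, n_vars)
    if write:
        write_pairs(pairs, outdir / "pairs.tsv")

    net = build_network(pairs, alpha_eff, nodes=[v.name for v in table.variables])
    giant, isolated = giant_component(net)
    mst = kruskal_mst(giant)
    if write:
        write_network(net, outdir / "network")
        write_network(mst, outdir / "mst")
        (outdir / "isolated_variables.txt").write_text("\n".join(isolated) + ("\n" if isolated else ""))

    full_assign = louvain_partition(giant, seed=config.louvain_seed, source="full")
    mst_assign = louvain_partition(mst, seed=config.louvain_seed, source="mst")
    induced = InducedClusterNetwork.from_assignment(
        mst, mst_assign, cutoff=config.centrality_cutoff
    )
    report = match_clusters(mst_assign, full_assign,
                            average_method=config.ami_average_method)

    manifest = {
        "phenonet_version": __version__,
        "config_hash": _config_hash(config),
        "alpha": config.alpha,
        "alpha_eff": alpha_eff,
        "min_n": config.min_n,
        "louvain_seed": config.louvain_seed,
        "n_subjects": table.n_subjects,
        "n_variables": n_vars,
        "n_pairs": len(pairs),
        "n_pairs_ok": sum(p.status == "ok" for p in pairs),
        "n_significant_edges": net.number_of_edges(),
        "giant_component_size": giant.number_of_nodes(),
        "n_isolated": len(isolated),
        "n_clusters_full": full_assign.n_clusters,
        "n_clusters_mst": mst_assign.n_clusters,
        "modularity_full": full_assign.modularity,
        "modularity_mst": mst_assign.modularity,
        "ami_mst_vs_full": report.ami,
        "relation_counts": report.relation_counts,
    }
    if truth is not None:
        gc_nodes = sorted(giant.nodes)
        manifest["ami_mst_vs_truth"] = adjusted_mutual_information(
            [mst_assign.labels[n] for n in gc_nodes],
            [truth.block_label[n] for n in gc_nodes],
        )
        manifest["ami_full_vs_truth"] = adjusted_mutual_information(
            [full_assign.labels[n] for n in gc_nodes],
            [truth.block_label[n] for n in gc_nodes],
        )

    if write:
        _write_cluster_artifacts(outdir, full_assign, mst_assign, induced, report)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        table=table, truth=truth, pairs=pairs, alpha_eff=alpha_eff,
        network=net, giant=giant, isolated=isolated, mst=mst,
        full_assign=full_assign, mst_assign=mst_assign, induced=induced,
        correspondence=report, manifest=manifest,
    )


def _write_cluster_artifacts(outdir: Path, full_assign: ClusterAssignment,
                             mst_assign: ClusterAssignment,
                             induced: InducedClusterNetwork,
                             report: CorrespondenceReport) -> None:
    rows = [
        {"variable": n, "cluster_id": cid, "source": assign.source}
        for assign in (full_assign, mst_assign)
        for n, cid in sorted(assign.labels.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    nx.write_graphml(induced.graph, outdir / "induced.graphml")
    nx.write_gexf(induced.graph, outdir / "induced.gexf")
    summary = {
        "modularity": {full_assign.source: full_assign.modularity,
                       mst_assign.source: mst_assign.modularity},
        "cluster_sizes_mst": {str(cid): len(m) for cid, m in sorted(mst_assign.clusters().items())},
        "betweenness": {str(c): bc for c, bc in sorted(induced.bc.items())},
        "centrality_class": {str(c): k for c, k in sorted(induced.centrality_class.items())},
    }
    with open(outdir / "cluster_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    report.write(outdir / "correspondence.tsv", outdir / "correspondence_summary.json")
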
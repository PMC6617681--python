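"""End-to-end orchestration: seeds → neighborhoods → network → clusters
→ heatmap → enrichment, with a run report of counts at every stage.

All analysis stages are deterministic; randomness exists only in the
synthetic-data generator.  Every intermediate can be written as TSV so
a run is inspectable and re-startable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from sklearn.metrics import adjusted_rand_score

from . import clustering, coexpression, enrichment, expression
from .clustering import BIN_LABEL, ClusterRelations, SeedNetwork
from .enrichment import GeneSetCollection
from .errors import ValidationError
from .expression import ExpressionMatrix, HeatmapMatrix
from .genelists import GeneList
from .synthetic import SyntheticTruth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the analysis with their standard defaults:
    top 40 co-expressed genes per seed, edge threshold r = 0.65, named
    clusters at ≥5 members, significance at −log10 p ≥ 1.3, intensity
    floor 1.0."""

    top_k: int = 40
    corr_method: str = "pearson"
    r_min: float = 0.65
    size_min: int = 5
    neglogp_threshold: float = 1.3
    pseudocount: float = 1.0
    seed: int = 0  # used by simulation only; analysis is deterministic

    def __post_init__(self) -> None:
        if self.top_k < 1 or self.size_min < 1:
            raise ValidationError("top_k and size_min must be >= 1")
        if not 0.0 < self.r_min < 1.0:
            raise ValidationError("r_min must lie in (0, 1)")
        if self.pseudocount <= 0 or self.neglogp_threshold <= 0:
            raise ValidationError("pseudocount and neglogp_threshold must be > 0")


@dataclass
class RunReport:
    """Counts and derived quantities from one pipeline run."""

    n_seeds: int = 0
    n_seeds_found: int = 0
    n_seeds_missing: int = 0
    pct_seeds_missing: float = 0.0
    n_seed_probes: int = 0
    n_edges: int = 0
    n_clusters: int = 0
    n_named_clusters: int = 0
    n_bins: int = 0
    anticorrelated_pairs: list[tuple[str, str]] = field(default_factory=list)
    n_significant_sets: int = 0
    ari_vs_truth: float | None = None
    config: dict = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class RunResult:
    """Report plus the in-memory artifacts of each stage."""

    report: RunReport
    mapping: expression.SeedMapping
    profiles: list[coexpression.NeighborhoodProfile]
    overlaps: coexpression.OverlapTable
    network: SeedNetwork
    relations: ClusterRelations | None
    heatmap: HeatmapMatrix
    enrichment_results: list[enrichment.EnrichmentResult] | None


def recovery_ari(
    truth: SyntheticTruth, matrix: ExpressionMatrix, network: SeedNetwork
) -> float:
    """Adjusted Rand index between planted and recovered partitions.

    Bins are singletons on both sides, so a bin absorbed into a cluster
    (or a cluster split apart) costs agreement.
    """
    truth_labels = truth.probe_truth_labels(network.nodes, matrix.probe_to_gene)
    rec = network.assignments
    probes = [p for p in network.nodes if p in truth_labels]
    t = [truth_labels[p] for p in probes]
    r = [f"rbin::{p}" if rec[p] == BIN_LABEL else rec[p] for p in probes]
    return float(adjusted_rand_score(t, r))


def run(
    matrix: ExpressionMatrix,
    seeds: GeneList,
    config: RunConfig = RunConfig(),
    genesets: GeneSetCollection | None = None,
    universe: list[str] | None = None,
    truth: SyntheticTruth | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Execute the full analysis and return report + artifacts.

    Stages: map seeds onto probes (aborts if none match), compute top-K
    co-expression neighborhoods, pairwise neighborhood overlaps, the
    thresholded network and its clusters/bins, cluster anti-correlation,
    the geometric-mean-centered heatmap matrix, and (when gene sets are
    supplied) Fisher over-representation of the seed list.
    """
    report = RunReport(config=dataclasses.asdict(config))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def emit(name: str, writer, *args) -> None:
        if out is not None:
            path = out / name
            writer(*args, path)
            report.manifest[name] = str(path)

    mapping = expression.map_seeds(matrix, seeds)
    report.n_seeds = len(seeds)
    report.n_seeds_found = len(mapping.seeds_found)
    report.n_seeds_missing = len(mapping.seeds_missing)
    report.pct_seeds_missing = mapping.missing_pct
    report.n_seed_probes = len(mapping.seed_probes)
    if not mapping.seed_probes:
        raise ValidationError("no seed gene is present in the expression matrix")

    profiles = coexpression.all_neighborhoods(
        matrix, mapping.seed_probes, k=config.top_k, method=config.corr_method
    )
    overlaps = coexpression.neighborhood_overlaps(profiles)
    network = clustering.build_network(overlaps, matrix, r_min=config.r_min)
    network = clustering.assign_clusters(network, overlaps, size_min=config.size_min)
    report.n_edges = len(network.edges)
    report.n_clusters = len(network.clusters)
    report.n_named_clusters = len(network.named_clusters)
    report.n_bins = len(network.bins)

    relations = None
    if len(network.clusters) >= 2:
        relations = clustering.cluster_relations(network, matrix)
        report.anticorrelated_pairs = [list(p) for p in relations.anticorrelated_pairs]

    seed_values = matrix.values.loc[list(mapping.seed_probes)]
    seed_matrix = ExpressionMatrix(
        seed_values,
        {p: matrix.probe_to_gene[p] for p in mapping.seed_probes},
        dict(matrix.sample_to_group),
    )
    heatmap = expression.center_log2(seed_matrix)
    heatmap = expression.order_heatmap(
        heatmap, network.assignments, matrix.probe_to_gene, matrix.sample_to_group
    )

    enrich_results = None
    if genesets is not None:
        enrich_results = enrichment.fisher_enrichment(
            seeds, genesets, threshold=config.neglogp_threshold, universe=universe
        )
        report.n_significant_sets = sum(r.significant for r in enrich_results)

    if truth is not None:
        report.ari_vs_truth = recovery_ari(truth, matrix, network)

    emit("neighborhoods.tsv", coexpression.write_neighborhoods, profiles)
    emit("overlap_table.tsv", coexpression.write_overlap_table, overlaps)
    emit("edges.tsv", clustering.write_edge_list, network)
    emit("network.graphml", clustering.write_graphml, network)
    emit("clusters.tsv", clustering.write_cluster_assignments, network)
    emit("heatmap.tsv", expression.write_heatmap, heatmap)
    if enrich_results is not None:
        emit("enrichment.tsv", enrichment.write_enrichment, enrich_results)
    if out is not None:
        report.to_json(out / "report.json")
        report.manifest["report.json"] = str(out / "report.json")

    logger.info(
        "run: %d seeds (%d found, %d missing), %d probes, %d clusters "
        "(%d named), %d bins, %d edges",
        report.n_seeds, report.n_seeds_found, report.n_seeds_missing,
        report.n_seed_probes, report.n_clusters, report.n_named_clusters,
        report.n_bins, report.n_edges,
    )
    return RunResult(
        report=report,
        mapping=mapping,
        profiles=profiles,
        overlaps=overlaps,
        network=network,
        relations=relations,
        heatmap=heatmap,
        enrichment_results=enrich_results,
    )
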
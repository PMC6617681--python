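"""Seed similarity network, cluster assignment, and cluster relations.

Seeds are connected when their top-K neighborhoods share at least one
gene AND their expression profiles correlate at or above a threshold
(default r = 0.65, a strong positive relationship).  Clusters are the
connected components of that graph; a seed whose neighborhood shares no
gene with any other seed's is an unclustered "bin" gene.  Clusters with
at least ``size_min`` members (default 5) are the "named" clusters.
Cluster mean profiles are then compared pairwise to detect
anti-correlated cluster pairs — clusters with opposite expression
profiles across the cell lineages.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import OverlapTable, correlation_rows
from .errors import ValidationError
from .expression import ExpressionMatrix, HeatmapMatrix, center_log2

BIN_LABEL = "bin"

DEFAULT_R_MIN = 0.65
DEFAULT_SIZE_MIN = 5


def cluster_labels(n: int) -> list[str]:
    """A, B, …, Z, AA, AB, … — spreadsheet-style labels."""
    labels = []
    alphabet = [chr(ord("A") + i) for i in range(26)]
    width = 1
    while len(labels) < n:
        labels.extend("".join(t) for t in itertools.product(alphabet, repeat=width))
        width += 1
    return labels[:n]


@dataclass(frozen=True)
class Edge:
    u: str
    v: str
    overlap_count: int
    profile_correlation: float


@dataclass(frozen=True)
class SeedNetwork:
    """Weighted seed-probe graph with cluster assignments.

    ``clusters`` maps label → member probes (labels in decreasing size
    order, A = largest; ties broken by the alphabetically smallest
    member gene symbol).  ``bins`` are probes with zero neighborhood
    overlap against every other seed.  ``clusters`` and ``bins``
    partition the nodes.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    r_min: float
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    clusters: dict[str, tuple[str, ...]] = field(default_factory=dict)
    bins: tuple[str, ...] = ()
    size_min: int = DEFAULT_SIZE_MIN

    @property
    def named_clusters(self) -> tuple[str, ...]:
        return tuple(
            label
            for label, members in self.clusters.items()
            if len(members) >= self.size_min
        )

    @property
    def assignments(self) -> dict[str, str]:
        """probe → cluster label or ``bin``."""
        out = {p: BIN_LABEL for p in self.bins}
        for label, members in self.clusters.items():
            out.update({p: label for p in members})
        return out

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.u, e.v,
                overlap_count=e.overlap_count,
                correlation=e.profile_correlation,
                weight=e.overlap_count,
            )
        return g


def build_network(
    overlaps: OverlapTable,
    matrix,
    r_min: float = DEFAULT_R_MIN,
    probe_to_gene: Mapping[str, str] | None = None,
) -> SeedNetwork:
    """Edges between seed pairs with ≥1 shared neighbor gene and profile
    correlation ≥ *r_min*.

    Both signals are required: the neighborhood overlap ties seeds to a
    shared co-expression neighborhood, while the profile-correlation
    threshold keeps only strong positive relationships.  Edge weight is
    the overlap count.
    """
    if not 0.0 < r_min < 1.0:
        raise ValidationError(f"r_min must lie in (0, 1), got {r_min}")
    seeds = [str(p) for p in overlaps.counts.index]
    corr = correlation_rows(matrix, seeds)[seeds]
    genes = dict(probe_to_gene) if probe_to_gene is not None else (
        dict(matrix.probe_to_gene) if isinstance(matrix, ExpressionMatrix) else {}
    )
    edges = []
    counts = overlaps.counts
    for i, u in enumerate(seeds):
        for v in seeds[i + 1 :]:
            c = int(counts.loc[u, v])
            r = float(corr.loc[u, v])
            if c >= 1 and r >= r_min:
                edges.append(Edge(u, v, c, r))
    return SeedNetwork(
        nodes=tuple(seeds), edges=tuple(edges), r_min=r_min, probe_to_gene=genes
    )


def assign_clusters(
    network: SeedNetwork,
    overlaps: OverlapTable,
    size_min: int = DEFAULT_SIZE_MIN,
) -> SeedNetwork:
    """Fill in clusters and bins from the edge graph.

    Clusters are connected components (≥2 members) plus singleton
    clusters for seeds that overlap someone but kept no edge; seeds
    with zero overlap against every other seed become bins —
    "bin" status is decided by overlap alone, not by the correlation
    threshold.
    """
    counts = overlaps.counts
    off_diag = counts.to_numpy().copy()
    np.fill_diagonal(off_diag, 0)
    has_overlap = {
        probe: bool(off_diag[i].sum() > 0) for i, probe in enumerate(counts.index)
    }
    g = network.graph()
    components = [set(c) for c in nx.connected_components(g)]
    member_sets: list[tuple[str, ...]] = []
    bins: list[str] = []
    for comp in components:
        if len(comp) >= 2:
            member_sets.append(tuple(sorted(comp)))
        else:
            (probe,) = comp
            if has_overlap.get(probe, False):
                member_sets.append((probe,))
            else:
                bins.append(probe)

    def smallest_symbol(members: tuple[str, ...]) -> str:
        return min(network.probe_to_gene.get(p, p) for p in members)

    member_sets.sort(key=lambda m: (-len(m), smallest_symbol(m)))
    labels = cluster_labels(len(member_sets))
    clusters = {lab: members for lab, members in zip(labels, member_sets)}
    return replace(
        network, clusters=clusters, bins=tuple(sorted(bins)), size_min=size_min
    )


@dataclass(frozen=True)
class ClusterRelations:
    """Pairwise correlations between cluster mean expression profiles."""

    pair_correlations: pd.DataFrame
    anticorrelated_pairs: tuple[tuple[str, str], ...]


def cluster_relations(network: SeedNetwork, matrix) -> ClusterRelations:
    """Correlate cluster mean log2-deviation profiles; flag pairs at or
    below −r_min as anti-correlated (opposite expression profiles)."""
    if len(network.clusters) < 2:
        raise ValidationError("need at least 2 clusters to relate")
    if isinstance(matrix, ExpressionMatrix):
        dev = center_log2(matrix).deviations
    elif isinstance(matrix, HeatmapMatrix):
        dev = matrix.deviations
    else:
        dev = matrix.sub(matrix.mean(axis=1), axis=0)
    labels = sorted(network.clusters)
    profiles = pd.DataFrame(
        {lab: dev.loc[list(network.clusters[lab])].mean(axis=0) for lab in labels}
    ).T
    if (np.ptp(profiles.to_numpy(), axis=1) == 0).any():
        warnings.warn("constant cluster profile: correlations reported as 0")
    corr = correlation_rows(profiles, labels)[labels]
    np.fill_diagonal(corr.values, 1.0)
    flagged = tuple(
        (a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
        if corr.loc[a, b] <= -network.r_min
    )
    return ClusterRelations(corr, flagged)


def write_edge_list(network: SeedNetwork, path: str | Path) -> None:
    rows = [
        (e.u, e.v, e.overlap_count, f"{e.profile_correlation:.6f}")
        for e in network.edges
    ]
    pd.DataFrame(
        rows, columns=["seed_i", "seed_j", "overlap_count", "correlation"]
    ).to_csv(path, sep="\t", index=False)


def write_graphml(network: SeedNetwork, path: str | Path) -> None:
    g = network.graph()
    assignments = network.assignments
    for node in g.nodes:
        g.nodes[node]["gene"] = network.probe_to_gene.get(node, node)
        g.nodes[node]["cluster"] = assignments.get(node, BIN_LABEL)
    nx.write_graphml(g, path)


def write_cluster_assignments(network: SeedNetwork, path: str | Path) -> None:
    rows = [
        (p, network.probe_to_gene.get(p, p), label)
        for p, label in sorted(network.assignments.items())
    ]
    pd.DataFrame(rows, columns=["probe", "gene", "cluster"]).to_csv(
        path, sep="\t", index=False
    )
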
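"""Seed network construction, cluster assignment, and cluster relations."""

import numpy as np
import pandas as pd
import pytest

import seedclust as sc
from seedclust.clustering import (
    assign_clusters,
    build_network,
    cluster_labels,
    cluster_relations,
    write_cluster_assignments,
    write_edge_list,
    write_graphml,
)
from seedclust.coexpression import OverlapTable, all_neighborhoods, neighborhood_overlaps
from seedclust.errors import ValidationError

from conftest import naive_pearson


def _overlaps(names, counts, k=5):
    df = pd.DataFrame(np.asarray(counts, dtype=int), index=names, columns=names)
    return OverlapTable(df, k)


def _df(arr, probes):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr, index=probes, columns=[f"s{j}" for j in range(arr.shape[1])]
    )


class TestBuildNetwork:
    def test_edge_requires_both_overlap_and_correlation(self):
        # a~b perfectly correlated with shared neighbors; a~c overlap but
        # weak correlation; b~c correlated but no overlap
        probes = ["a", "b", "c"]
        df = _df([[1, 2, 3, 4], [2, 4, 6, 8], [4, 1, 5, 2]], probes)
        counts = [[5, 3, 2], [3, 5, 0], [2, 0, 5]]
        net = build_network(_overlaps(probes, counts), df, r_min=0.65)
        pairs = {(e.u, e.v) for e in net.edges}
        assert pairs == {("a", "b")}
        (edge,) = net.edges
        assert edge.profile_correlation == pytest.approx(1.0, abs=1e-12)
        assert edge.overlap_count == 3

    def test_r_min_outside_unit_interval_rejected(self):
        probes = ["a", "b"]
        df = _df([[1, 2, 3], [1, 2, 3]], probes)
        ov = _overlaps(probes, [[5, 1], [1, 5]])
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValidationError):
                build_network(ov, df, r_min=bad)

    def test_raising_r_min_never_creates_edges(self, noiseless):
        _, matrix, seeds, _ = noiseless
        mapping = sc.map_seeds(matrix, seeds)
        probes = list(mapping.seed_probes)[:40]
        profiles = all_neighborhoods(matrix, probes, k=40)
        ov = neighborhood_overlaps(profiles)
        edge_sets = []
        for r_min in (0.5, 0.65, 0.8):
            net = build_network(ov, matrix, r_min=r_min)
            edge_sets.append({(e.u, e.v) for e in net.edges})
        assert edge_sets[2] <= edge_sets[1] <= edge_sets[0]

    def test_edges_match_brute_force_oracle(self, noiseless):
        _, matrix, seeds, _ = noiseless
        mapping = sc.map_seeds(matrix, seeds)
        probes = list(mapping.seed_probes)[:25]
        profiles = all_neighborhoods(matrix, probes, k=40)
        ov = neighborhood_overlaps(profiles)
        net = build_network(ov, matrix, r_min=0.65)
        log2 = matrix.log2()
        expected = set()
        for i, u in enumerate(probes):
            for v in probes[i + 1 :]:
                r = naive_pearson(log2.loc[u].tolist(), log2.loc[v].tolist())
                if ov.counts.loc[u, v] >= 1 and r >= 0.65 - 1e-12:
                    expected.add((u, v))
        assert {(e.u, e.v) for e in net.edges} == expected


class TestAssignClusters:
    def test_all_zero_overlap_means_all_bins(self):
        probes = ["a", "b", "c"]
        df = _df(np.random.default_rng(0).normal(size=(3, 5)), probes)
        counts = np.zeros((3, 3), int)
        np.fill_diagonal(counts, 5)
        net = build_network(_overlaps(probes, counts), df)
        net = assign_clusters(net, _overlaps(probes, counts))
        assert net.clusters == {}
        assert set(net.bins) == set(probes)

    def test_chain_forms_single_component(self):
        probes = ["a", "b", "c"]
        df = _df([[1, 2, 3, 4]] * 3, probes)
        counts = [[5, 1, 0], [1, 5, 1], [0, 1, 5]]
        ov = _overlaps(probes, counts)
        net = assign_clusters(build_network(ov, df), ov)
        assert net.clusters == {"A": ("a", "b", "c")}
        assert net.bins == ()

    def test_overlapping_but_uncorrelated_seed_is_singleton_cluster_not_bin(self):
        probes = ["a", "b", "c"]
        df = _df([[1, 2, 3, 4], [2, 4, 6, 8], [4, 1, 5, 2]], probes)
        counts = [[5, 3, 2], [3, 5, 0], [2, 0, 5]]
        ov = _overlaps(probes, counts)
        net = assign_clusters(build_network(ov, df), ov)
        labels = net.assignments
        assert labels["c"] != "bin"
        assert len(net.clusters) == 2  # {a,b} and {c}
        assert net.bins == ()

    def test_labels_in_decreasing_size_order(self, noiseless_run):
        *_, result = noiseless_run
        sizes = [len(m) for m in result.network.clusters.values()]
        assert sizes == sorted(sizes, reverse=True)
        assert list(result.network.clusters) == cluster_labels(len(sizes))

    def test_partition_property(self, noiseless_run):
        *_, result = noiseless_run
        net = result.network
        total = len(net.bins) + sum(len(m) for m in net.clusters.values())
        assert total == len(net.nodes)
        members = [p for m in net.clusters.values() for p in m] + list(net.bins)
        assert sorted(members) == sorted(net.nodes)

    def test_component_labels_invariant_under_node_permutation(self):
        rng = np.random.default_rng(13)
        probes = [f"p{i}" for i in range(8)]
        base = rng.normal(size=(4, 6))
        arr = np.vstack([base[i // 2] + rng.normal(0, 0.05, 6) for i in range(8)])
        df = _df(arr, probes)
        profiles = all_neighborhoods(df, probes, k=3)
        ov = neighborhood_overlaps(profiles)
        net1 = assign_clusters(build_network(ov, df), ov)
        perm = rng.permutation(8)
        df2 = df.iloc[perm]
        ov2 = OverlapTable(
            ov.counts.iloc[perm, :].iloc[:, perm], ov.k
        )
        net2 = assign_clusters(build_network(ov2, df2), ov2)
        assert net1.assignments == net2.assignments

    def test_named_clusters_respect_size_min(self, noiseless_run):
        *_, result = noiseless_run
        net = result.network
        for label in net.named_clusters:
            assert len(net.clusters[label]) >= net.size_min
        for label in set(net.clusters) - set(net.named_clusters):
            assert len(net.clusters[label]) < net.size_min


class TestClusterRelations:
    def test_opposite_profiles_flagged(self):
        probes = ["a1", "a2", "b1", "b2"]
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        df = _df(np.vstack([x, x, -x + 7, -x + 7]) + 10, probes)
        counts = [[5, 2, 0, 0], [2, 5, 0, 0], [0, 0, 5, 2], [0, 0, 2, 5]]
        ov = _overlaps(probes, counts)
        net = assign_clusters(build_network(ov, df), ov)
        rel = cluster_relations(net, df)
        assert rel.anticorrelated_pairs == (("A", "B"),)
        assert rel.pair_correlations.loc["A", "B"] == pytest.approx(-1.0, abs=1e-9)

    def test_identical_profiles_not_flagged(self):
        probes = ["a1", "a2", "b1", "b2"]
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        df = _df(np.vstack([x, x, x, x]) + 10, probes)
        counts = [[5, 2, 0, 0], [2, 5, 0, 0], [0, 0, 5, 2], [0, 0, 2, 5]]
        ov = _overlaps(probes, counts)
        net = assign_clusters(build_network(ov, df), ov)
        rel = cluster_relations(net, df)
        assert rel.anticorrelated_pairs == ()
        assert rel.pair_correlations.loc["A", "B"] == pytest.approx(1.0, abs=1e-9)

    def test_matrix_symmetric_with_unit_diagonal(self, noiseless_run):
        *_, result = noiseless_run
        corr = result.relations.pair_correlations
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)

    def test_requires_two_clusters(self):
        probes = ["a", "b"]
        df = _df([[1, 2, 3], [1, 2, 3]], probes)
        ov = _overlaps(probes, [[5, 1], [1, 5]])
        net = assign_clusters(build_network(ov, df), ov)
        with pytest.raises(ValidationError):
            cluster_relations(net, df)


def test_cluster_label_sequence():
    labels = cluster_labels(30)
    assert labels[:3] == ["A", "B", "C"]
    assert labels[25] == "Z" and labels[26] == "AA"
    assert len(set(labels)) == 30


def test_exports_are_readable(tmp_path, noiseless_run):
    *_, result = noiseless_run
    write_edge_list(result.network, tmp_path / "edges.tsv")
    write_cluster_assignments(result.network, tmp_path / "clusters.tsv")
    write_graphml(result.network, tmp_path / "net.graphml")
    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert set(edges.columns) == {"seed_i", "seed_j", "overlap_count", "correlation"}
    assert (edges["correlation"] >= 0.65).all()
    clusters = pd.read_csv(tmp_path / "clusters.tsv", sep="\t")
    assert len(clusters) == len(result.network.nodes)
    import networkx as nx

    g = nx.read_graphml(tmp_path / "net.graphml")
    assert g.number_of_nodes() == len(result.network.nodes)
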
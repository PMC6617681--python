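"""Expression IO, seed mapping, and geometric-mean log2 centering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import seedclust as sc
from seedclust.errors import ParseError, ValidationError
from seedclust.expression import (
    ExpressionMatrix,
    center_log2,
    map_seeds,
    order_heatmap,
    read_expression,
    write_expression,
    write_sample_groups,
)
from seedclust.genelists import GeneList


def _write_table(path, text):
    path.write_text(text)
    return path


class TestReadExpression:
    def test_tsv_with_gene_column(self, tmp_path):
        p = _write_table(
            tmp_path / "m.tsv",
            "probe\tgene\ts1\ts2\ts3\ts4\n"
            "p1\tGA\t1\t2\t3\t4\n"
            "p2\tGB\t2\t2\t2\t2\n"
            "p3\tGA\t5\t6\t7\t8\n",
        )
        m = read_expression(p)
        assert m.shape == (3, 4)
        assert m.probe_to_gene == {"p1": "GA", "p2": "GB", "p3": "GA"}

    def test_csv_dialect(self, tmp_path):
        p = _write_table(tmp_path / "m.csv", "probe,s1,s2,s3\np1,1,2,3\n")
        assert read_expression(p, dialect="csv", gene_column=None).shape == (1, 3)

    def test_pseudocount_floors_and_counts(self, tmp_path):
        p = _write_table(
            tmp_path / "m.tsv", "probe\ts1\ts2\ts3\np1\t0\t2\t3\np2\t-1\t\t4\n"
        )
        m = read_expression(p, gene_column=None, pseudocount=1.0)
        assert m.n_floored == 3
        assert m.values.loc["p1", "s1"] == 1.0
        assert (m.values.to_numpy() > 0).all()

    def test_duplicate_probe_ids_rejected(self, tmp_path):
        p = _write_table(
            tmp_path / "m.tsv", "probe\ts1\ts2\ts3\np1\t1\t2\t3\np1\t4\t5\t6\n"
        )
        with pytest.raises(ValidationError, match="duplicate probe"):
            read_expression(p, gene_column=None)

    def test_non_numeric_cell_reports_location(self, tmp_path):
        p = _write_table(
            tmp_path / "m.tsv", "probe\ts1\ts2\ts3\np1\t1\toops\t3\n"
        )
        with pytest.raises(ParseError, match="'oops'.*'p1'.*'s2'"):
            read_expression(p, gene_column=None)

    def test_sidecar_maps(self, tmp_path):
        p = _write_table(tmp_path / "m.tsv", "probe\ts1\ts2\ts3\np1\t1\t2\t3\n")
        gm = _write_table(tmp_path / "g.tsv", "p1\tmygene\n")
        sm = _write_table(tmp_path / "s.tsv", "s1\tB\ns2\tB\ns3\tT\n")
        m = read_expression(p, gene_column=None, probe_gene_path=gm, sample_group_path=sm)
        assert m.probe_to_gene["p1"] == "MYGENE"
        assert m.sample_to_group == {"s1": "B", "s2": "B", "s3": "T"}

    def test_geo_series_matrix_dialect(self, tmp_path):
        p = _write_table(
            tmp_path / "m.txt",
            "!Series_title\t\"demo\"\n"
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"\n'
            '"p1"\t1.5\t2.5\t3.5\n'
            "!series_matrix_table_end\n",
        )
        m = read_expression(p, dialect="geo_series_matrix", gene_column=None)
        assert m.shape == (1, 3)
        assert m.sample_ids == ("GSM1", "GSM2", "GSM3")

    def test_synthetic_round_trip(self, tmp_path, noiseless):
        _, matrix, _, _ = noiseless
        sub = ExpressionMatrix(
            matrix.values.iloc[:25],
            {p: matrix.probe_to_gene[p] for p in matrix.probe_ids[:25]},
            dict(matrix.sample_to_group),
        )
        write_expression(sub, tmp_path / "m.tsv")
        write_sample_groups(sub, tmp_path / "groups.tsv")
        back = read_expression(
            tmp_path / "m.tsv", sample_group_path=tmp_path / "groups.tsv"
        )
        pd.testing.assert_frame_equal(back.values, sub.values)
        assert back.probe_to_gene == sub.probe_to_gene
        assert back.sample_to_group == sub.sample_to_group


class TestMapSeeds:
    def test_partition_and_multiprobe_enumeration(self, tiny_matrix):
        seeds = GeneList("s", ("GA", "GB", "GHOST"))
        mapping = map_seeds(tiny_matrix, seeds)
        assert set(mapping.seeds_found) | set(mapping.seeds_missing) == set(seeds)
        assert not set(mapping.seeds_found) & set(mapping.seeds_missing)
        assert mapping.seeds_missing == ("GHOST",)
        assert set(mapping.seed_probes) == {"P1", "P2"}

    def test_all_found_when_fully_annotated(self, tiny_matrix):
        mapping = map_seeds(tiny_matrix, GeneList("s", ("GA", "GE")))
        assert mapping.seeds_missing == ()

    def test_idempotent(self, tiny_matrix):
        seeds = GeneList("s", ("GA", "GHOST"))
        assert map_seeds(tiny_matrix, seeds) == map_seeds(tiny_matrix, seeds)

    def test_planted_absent_count_recovered(self, noiseless):
        spec, matrix, seeds, truth = noiseless
        mapping = map_seeds(matrix, seeds)
        assert len(mapping.seeds_missing) == spec.n_absent
        assert set(mapping.seeds_missing) == {
            g for g, lab in truth.assignment.items() if lab == "absent"
        }
        assert mapping.missing_pct == 9.4

    def test_multiprobe_seeds_expand_probe_list(self, noiseless):
        spec, matrix, seeds, _ = noiseless
        mapping = map_seeds(matrix, seeds)
        assert len(mapping.seed_probes) == len(mapping.seeds_found) + spec.n_extra_probes


class TestCenterLog2:
    def test_constant_row_maps_to_zero(self):
        m = ExpressionMatrix(
            pd.DataFrame([[5.0, 5.0, 5.0]], index=["p"], columns=list("abc"))
        )
        assert np.allclose(center_log2(m).deviations.to_numpy(), 0.0)

    def test_powers_of_two(self):
        m = ExpressionMatrix(
            pd.DataFrame([[2.0, 8.0]], index=["p"], columns=["a", "b"])
        )
        assert np.allclose(center_log2(m).deviations.to_numpy(), [[-1.0, 1.0]])

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(3)
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.lognormal(2, 1, size=(10, 6)),
                index=[f"p{i}" for i in range(10)],
                columns=[f"s{j}" for j in range(6)],
            )
        )
        sums = center_log2(m).deviations.sum(axis=1).to_numpy()
        assert np.abs(sums).max() < 1e-9

    def test_invariant_to_row_scaling(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(2, 1, size=(5, 8))
        cols = [f"s{j}" for j in range(8)]
        idx = [f"p{i}" for i in range(5)]
        m1 = ExpressionMatrix(pd.DataFrame(base, index=idx, columns=cols))
        m2 = ExpressionMatrix(pd.DataFrame(base * 7.3, index=idx, columns=cols))
        np.testing.assert_allclose(
            center_log2(m1).deviations.to_numpy(),
            center_log2(m2).deviations.to_numpy(),
            atol=1e-9,
        )

    @settings(derandomize=True, max_examples=40)
    @given(
        arrays(
            np.float64,
            (4, 5),
            elements=st.floats(min_value=0.01, max_value=1e6),
        )
    )
    def test_row_sum_zero_for_arbitrary_positive_matrices(self, arr):
        m = ExpressionMatrix(
            pd.DataFrame(arr, index=[f"p{i}" for i in range(4)],
                         columns=[f"s{j}" for j in range(5)])
        )
        sums = center_log2(m).deviations.sum(axis=1).to_numpy()
        assert np.abs(sums).max() < 1e-9


class TestHeatmapOrdering:
    def test_rows_grouped_by_cluster_then_gene_bins_last(self, tiny_matrix):
        hm = center_log2(tiny_matrix)
        clusters = {"P1": "B", "P2": "A", "P3": "A", "P4": "bin"}
        ordered = order_heatmap(
            hm, clusters, tiny_matrix.probe_to_gene, tiny_matrix.sample_to_group
        )
        # A members by gene (GB < GC), then B, then unassigned/bins
        assert list(ordered.row_order)[:3] == ["P2", "P3", "P1"]
        assert set(ordered.row_order[3:]) == {"P4", "P5"}

    def test_columns_grouped_by_lineage(self, tiny_matrix):
        hm = order_heatmap(
            center_log2(tiny_matrix), {}, tiny_matrix.probe_to_gene,
            tiny_matrix.sample_to_group,
        )
        groups = [tiny_matrix.sample_to_group[s] for s in hm.column_order]
        assert groups == sorted(groups)


def test_matrix_rejects_non_positive_values():
    with pytest.raises(ValidationError):
        ExpressionMatrix(
            pd.DataFrame([[1.0, 0.0]], index=["p"], columns=["a", "b"])
        )
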
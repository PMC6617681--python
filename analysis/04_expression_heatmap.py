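"""Render the cluster-ordered heatmap of seed-gene expression.

Rows are seed probes expressed as log2 deviations from their geometric
mean (red above, blue below), grouped by cluster label with bins last;
columns are samples grouped by cell lineage.  Requires the outputs of
steps 01 and 03.  Writes the matrix TSV and a PNG to results/heatmap/.
"""

import argparse
from pathlib import Path

import pandas as pd

import seedclust as sc
from seedclust import expression

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=ROOT / "results" / "synthetic")
    parser.add_argument("--clusters", type=Path,
                        default=ROOT / "results" / "clusters" / "clusters.tsv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "heatmap")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = sc.read_expression(
        args.sim / "expression.tsv",
        sample_group_path=args.sim / "sample_groups.tsv",
    )
    assignments = pd.read_csv(args.clusters, sep="\t")
    probe_cluster = dict(
        zip(assignments["probe"].astype(str), assignments["cluster"].astype(str))
    )
    seed_probes = [p for p in matrix.probe_ids if p in probe_cluster]
    seed_matrix = sc.ExpressionMatrix(
        matrix.values.loc[seed_probes],
        {p: matrix.probe_to_gene[p] for p in seed_probes},
        dict(matrix.sample_to_group),
    )
    hm = expression.center_log2(seed_matrix)
    hm = expression.order_heatmap(
        hm, probe_cluster, matrix.probe_to_gene, matrix.sample_to_group
    )
    expression.write_heatmap(hm, args.out / "heatmap.tsv")
    expression.plot_heatmap(hm, args.out / "heatmap.png")

    dev = hm.ordered()
    print(f"heatmap: {dev.shape[0]} seed probes x {dev.shape[1]} samples, "
          f"deviations in [{dev.to_numpy().min():.2f}, {dev.to_numpy().max():.2f}] "
          f"log2 units")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
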
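"""Top-K co-expression neighborhoods and their pairwise overlaps.

For every seed probe we rank all other probes by correlation of their
expression profiles across samples and keep the top K (default 40) —
the seed's co-expression neighborhood.  Genes recur in the
neighborhoods of functionally related seeds, so the size of the
gene-symbol intersection between two seeds' neighborhoods measures how
similarly the two seeds are expressed across cell lineages; those
counts feed the clustering network.

Correlation is Pearson on log2 intensities by default (Spearman is
available); overlap is counted on gene symbols, not probe ids, so two
seeds that co-express the same gene through different probes still
overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .expression import ExpressionMatrix, HeatmapMatrix

Method = Literal["pearson", "spearman"]

DEFAULT_TOP_K = 40


class Neighbor(NamedTuple):
    probe: str
    gene: str
    correlation: float


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Ranked top-K co-expressed genes of one seed probe."""

    seed_probe: str
    neighbors: tuple[Neighbor, ...]
    k: int
    method: str

    def __post_init__(self) -> None:
        probes = [n.probe for n in self.neighbors]
        if self.seed_probe in probes:
            raise ValidationError("seed probe cannot be its own neighbor")
        corrs = [n.correlation for n in self.neighbors]
        if any(c2 > c1 + 1e-12 for c1, c2 in zip(corrs, corrs[1:])):
            raise ValidationError("neighbor correlations must be non-increasing")

    @property
    def neighbor_genes(self) -> frozenset[str]:
        return frozenset(n.gene for n in self.neighbors)


def _surface(matrix) -> pd.DataFrame:
    """Correlation surface: log2 intensities, or deviations as given."""
    if isinstance(matrix, ExpressionMatrix):
        return matrix.log2()
    if isinstance(matrix, HeatmapMatrix):
        return matrix.deviations
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"unsupported matrix type: {type(matrix).__name__}")


def _gene_map(matrix, probe_to_gene) -> Mapping[str, str]:
    if probe_to_gene is not None:
        return probe_to_gene
    if isinstance(matrix, ExpressionMatrix):
        return matrix.probe_to_gene
    return {}


def _standardized(values: np.ndarray, method: Method) -> np.ndarray:
    """Rows as unit-norm centered vectors; constant rows become zero
    (their correlation with anything is reported as 0)."""
    if method == "spearman":
        values = rankdata(values, axis=1)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, centered / norms, 0.0)
    return z


def correlation_rows(
    matrix,
    seed_probes: Sequence[str],
    method: Method = "pearson",
) -> pd.DataFrame:
    """Correlations of each seed probe against every probe (seeds × probes).

    Vectorized: one matrix product over unit-norm centered rows.
    """
    df = _surface(matrix)
    missing = [p for p in seed_probes if p not in df.index]
    if missing:
        raise KeyError(f"seed probes absent from matrix: {missing[:5]}")
    if df.shape[1] < 3:
        raise ValidationError("need at least 3 samples to correlate")
    raw = df.to_numpy(dtype=float)
    z = _standardized(raw, method)
    idx = df.index.get_indexer(list(seed_probes))
    if np.any(np.ptp(raw[idx], axis=1) == 0.0):
        warnings.warn(
            "constant seed row(s): correlations reported as 0", stacklevel=2
        )
    corr = np.clip(z[idx] @ z.T, -1.0, 1.0)
    return pd.DataFrame(corr, index=list(seed_probes), columns=df.index)


def correlate_seed(matrix, seed_probe: str, method: Method = "pearson") -> pd.Series:
    """Correlation of one seed row against every *other* probe row."""
    row = correlation_rows(matrix, [seed_probe], method).iloc[0]
    return row.drop(index=seed_probe)


def _rank_top_k(
    corrs: pd.Series, k: int, gene_of: Mapping[str, str], method: str, seed_probe: str
) -> NeighborhoodProfile:
    probes = np.asarray(corrs.index, dtype=object)
    values = corrs.to_numpy(dtype=float)
    # primary key: descending correlation; ties: ascending probe id
    order = np.lexsort((probes, -values))
    top = order[: min(k, len(order))]
    neighbors = tuple(
        Neighbor(str(probes[i]), gene_of.get(str(probes[i]), str(probes[i])), float(values[i]))
        for i in top
    )
    return NeighborhoodProfile(seed_probe, neighbors, k, method)


def top_k_neighbors(
    matrix,
    seed_probe: str,
    k: int = DEFAULT_TOP_K,
    method: Method = "pearson",
    probe_to_gene: Mapping[str, str] | None = None,
) -> NeighborhoodProfile:
    """The seed's K most correlated probes, self excluded.

    Ties at the K-th correlation are broken by lexicographic probe id,
    so the result is deterministic and has exactly min(K, pool) entries.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    corrs = correlate_seed(matrix, seed_probe, method)
    return _rank_top_k(corrs, k, _gene_map(matrix, probe_to_gene), method, seed_probe)


def all_neighborhoods(
    matrix,
    seed_probes: Sequence[str],
    k: int = DEFAULT_TOP_K,
    method: Method = "pearson",
    probe_to_gene: Mapping[str, str] | None = None,
) -> list[NeighborhoodProfile]:
    """Top-K neighborhoods for many seeds at once (shared correlation pass)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    rows = correlation_rows(matrix, seed_probes, method)
    gene_of = _gene_map(matrix, probe_to_gene)
    return [
        _rank_top_k(rows.loc[p].drop(index=p), k, gene_of, method, p)
        for p in seed_probes
    ]


@dataclass(frozen=True)
class OverlapTable:
    """Symmetric seed × seed matrix of neighborhood gene-set overlaps.

    The diagonal is defined as K for completeness but never used when
    building network edges.
    """

    counts: pd.DataFrame
    k: int

    def pair(self, i: str, j: str) -> int:
        return int(self.counts.loc[i, j])


def neighborhood_overlaps(profiles: Iterable[NeighborhoodProfile]) -> OverlapTable:
    """Counts of shared neighbor genes for every pair of seed profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles supplied")
    ks = {p.k for p in profiles}
    methods = {p.method for p in profiles}
    if len(ks) != 1 or len(methods) != 1:
        raise ValidationError("profiles mix K or correlation method")
    k = ks.pop()
    seeds = [p.seed_probe for p in profiles]
    gene_sets = [p.neighbor_genes for p in profiles]
    n = len(seeds)
    counts = np.full((n, n), k, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            c = len(gene_sets[i] & gene_sets[j])
            counts[i, j] = counts[j, i] = c
    return OverlapTable(pd.DataFrame(counts, index=seeds, columns=seeds), k)


def write_neighborhoods(
    profiles: Iterable[NeighborhoodProfile], path: str | Path
) -> None:
    """Per-seed neighborhood TSV: seed, rank, probe, gene, correlation."""
    rows = []
    for p in profiles:
        for rank, nb in enumerate(p.neighbors, start=1):
            rows.append((p.seed_probe, rank, nb.probe, nb.gene, f"{nb.correlation:.6f}"))
    df = pd.DataFrame(rows, columns=["seed_probe", "rank", "probe", "gene", "correlation"])
    df.to_csv(path, sep="\t", index=False)


def write_overlap_table(table: OverlapTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "seed_probe"
    df.to_csv(path, sep="\t")
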
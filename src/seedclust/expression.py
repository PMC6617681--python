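"""Expression matrices, seed mapping, and geometric-mean log2 centering.

The pipeline operates on a probes × samples matrix of strictly positive
microarray-style intensities, annotated with a probe→gene map and a
sample→cell-lineage-group map (e.g. the 12 immune cell populations of a
mouse immune-compendium design).  Seed gene lists are mapped onto probes
by case-insensitive symbol match; seeds without any probe are "not
expressed" and excluded downstream.  For heatmap display each probe row
is expressed as log2 deviations from its geometric mean across samples,
so rows sum to zero in log space and red/blue encode above/below the
probe's typical level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .genelists import GeneList, round_half_up

logger = logging.getLogger(__name__)

UNANNOTATED = "UNANNOTATED"

Dialect = Literal["tsv", "csv", "geo_series_matrix"]


@dataclass
class ExpressionMatrix:
    """Probes × samples matrix of strictly positive intensities.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns.
    probe_to_gene
        Map probe → uppercase gene symbol.  Probes without an entry get
        the sentinel ``UNANNOTATED``.  Many probes may share a gene.
    sample_to_group
        Map sample → lineage-group label.
    n_floored
        Number of non-positive / missing cells replaced by the
        pseudocount floor at load time.
    """

    values: pd.DataFrame
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    sample_to_group: dict[str, str] = field(default_factory=dict)
    n_floored: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValidationError("intensities must be finite and strictly positive")
        self.probe_to_gene = {
            str(p): str(self.probe_to_gene.get(p, UNANNOTATED)).strip().upper()
            or UNANNOTATED
            for p in v.index
        }
        self.sample_to_group = {
            str(s): str(self.sample_to_group.get(s, "UNGROUPED")) for s in v.columns
        }

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_of(self, probe: str) -> str:
        return self.probe_to_gene.get(probe, UNANNOTATED)

    def log2(self) -> pd.DataFrame:
        """Log2-transformed intensities (the co-expression surface)."""
        return np.log2(self.values)


def _read_sidecar(path: str | Path) -> dict[str, str]:
    """Two-column TSV map (no header); '#' comment lines skipped."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: line {i}: expected two tab-separated fields")
        out[parts[0].strip()] = parts[1].strip()
    return out


def _geo_table_lines(path: Path) -> list[str]:
    """Extract the data table from a GEO series-matrix file.

    Metadata lines begin with ``!``; the expression table sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
    """
    lines = path.read_text().splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        if line.startswith("!series_matrix_table_begin"):
            begin = i + 1
        elif line.startswith("!series_matrix_table_end"):
            end = i
    if begin is None:
        # tolerate plain tables shipped with GEO-style "!" headers only
        table = [l for l in lines if l and not l.startswith("!")]
        if not table:
            raise ParseError(f"{path}: no series_matrix table found")
        return table
    return lines[begin:end]


def read_expression(
    path: str | Path,
    dialect: Dialect = "tsv",
    gene_column: str | None = "gene",
    probe_gene_path: str | Path | None = None,
    sample_group_path: str | Path | None = None,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Read an expression table into a validated :class:`ExpressionMatrix`.

    The first column holds probe ids; remaining columns are samples.  A
    column named *gene_column* (if present) provides the probe→gene
    annotation; a two-column sidecar given via *probe_gene_path*
    overrides it.  Sample→group labels come from *sample_group_path*.

    Non-positive or missing cells are floored to *pseudocount* (the
    conventional microarray intensity floor) and counted in
    ``n_floored``.
    """
    path = Path(path)
    sep = "," if dialect == "csv" else "\t"
    if dialect == "geo_series_matrix":
        from io import StringIO

        buf = StringIO("\n".join(_geo_table_lines(path)))
        df = pd.read_csv(buf, sep="\t", index_col=0, quotechar='"')
    else:
        df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')

    probe_to_gene: dict[str, str] = {}
    if gene_column is not None:
        hits = [c for c in df.columns if c.lower() == gene_column.lower()]
        if hits:
            probe_to_gene = df[hits[0]].astype(str).to_dict()
            df = df.drop(columns=hits)
    if probe_gene_path is not None:
        probe_to_gene.update(_read_sidecar(probe_gene_path))
    sample_to_group = (
        _read_sidecar(sample_group_path) if sample_group_path is not None else {}
    )

    # locate non-numeric cells precisely before coercing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at probe "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    arr = numeric.to_numpy(dtype=float)
    mask = ~np.isfinite(arr) | (arr <= 0)
    n_floored = int(mask.sum())
    if n_floored:
        arr = np.where(mask, pseudocount, arr)
        logger.info("%s: floored %d non-positive/missing cells to %g",
                    path, n_floored, pseudocount)
    values = pd.DataFrame(arr, index=df.index, columns=df.columns)
    values.index.name = None
    values.columns.name = None
    return ExpressionMatrix(values, probe_to_gene, sample_to_group, n_floored)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with a ``gene`` annotation column."""
    df = matrix.values.copy()
    df.insert(0, "gene", [matrix.probe_to_gene[p] for p in df.index])
    df.index.name = "probe"
    df.to_csv(path, sep="\t")


def write_sample_groups(matrix: ExpressionMatrix, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\t{g}\n" for s, g in matrix.sample_to_group.items())
    )


@dataclass(frozen=True)
class SeedMapping:
    """Partition of a seed list into expressed and absent symbols."""

    seeds_found: tuple[str, ...]
    seeds_missing: tuple[str, ...]
    seed_probes: tuple[str, ...]

    @property
    def missing_fraction(self) -> float:
        total = len(self.seeds_found) + len(self.seeds_missing)
        return len(self.seeds_missing) / total if total else 0.0

    @property
    def missing_pct(self) -> float:
        """Percent of seeds absent from the matrix, half-up to 1 decimal."""
        return round_half_up(100.0 * self.missing_fraction)


def map_seeds(matrix: ExpressionMatrix, seeds: GeneList) -> SeedMapping:
    """Map seed symbols onto probes by case-insensitive symbol match.

    Seeds without any probe are reported missing ("not expressed");
    every probe of every found seed is enumerated, so genes with
    multiple transcripts contribute multiple probes.
    """
    gene_to_probes: dict[str, list[str]] = {}
    for probe, gene in matrix.probe_to_gene.items():
        gene_to_probes.setdefault(gene, []).append(probe)
    found, missing, probes = [], [], []
    for sym in seeds:
        if sym in gene_to_probes:
            found.append(sym)
            probes.extend(sorted(gene_to_probes[sym]))
        else:
            missing.append(sym)
    if missing:
        logger.info(
            "map_seeds: %d/%d seeds not expressed (%.1f%%)",
            len(missing), len(seeds), 100.0 * len(missing) / len(seeds),
        )
    return SeedMapping(tuple(found), tuple(missing), tuple(probes))


@dataclass
class HeatmapMatrix:
    """Per-probe log2 deviations from the geometric mean across samples.

    ``deviations[p, s] = log2(x[p, s]) − mean_s log2(x[p, ·])``, i.e.
    ``log2(x / geometric_mean)``; each row sums to zero by identity.
    """

    deviations: pd.DataFrame
    row_order: tuple[str, ...]
    column_order: tuple[str, ...]

    def ordered(self) -> pd.DataFrame:
        return self.deviations.loc[list(self.row_order), list(self.column_order)]


def center_log2(matrix: ExpressionMatrix) -> HeatmapMatrix:
    """Geometric-mean-center the log2 intensities, probe by probe."""
    logged = matrix.log2()
    dev = logged.sub(logged.mean(axis=1), axis=0)
    return HeatmapMatrix(
        deviations=dev,
        row_order=tuple(dev.index),
        column_order=tuple(dev.columns),
    )


def order_heatmap(
    heatmap: HeatmapMatrix,
    probe_cluster: Mapping[str, str],
    probe_to_gene: Mapping[str, str],
    sample_to_group: Mapping[str, str],
    bin_label: str = "bin",
) -> HeatmapMatrix:
    """Order rows by cluster label (bins last), then gene symbol
    alphabetically; order columns by lineage group."""

    def row_key(probe: str) -> tuple:
        label = probe_cluster.get(probe, bin_label)
        return (label == bin_label, label, probe_to_gene.get(probe, probe), probe)

    rows = sorted(heatmap.deviations.index, key=row_key)
    cols = sorted(heatmap.deviations.columns, key=lambda s: (sample_to_group.get(s, ""), s))
    return HeatmapMatrix(heatmap.deviations, tuple(rows), tuple(cols))


def write_heatmap(heatmap: HeatmapMatrix, path: str | Path) -> None:
    df = heatmap.ordered()
    df.index.name = "probe"
    df.to_csv(path, sep="\t", float_format="%.6g")


def plot_heatmap(heatmap: HeatmapMatrix, path: str | Path) -> None:
    """Render the matrix with a diverging palette (red high, blue low)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = heatmap.ordered()
    lim = float(np.abs(df.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, df.shape[1] * 0.08), max(4, df.shape[0] * 0.04))
    )
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xlabel("samples (by lineage group)")
    ax.set_ylabel("probes (by cluster)")
    fig.colorbar(im, ax=ax, label="log2 deviation from geometric mean")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
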
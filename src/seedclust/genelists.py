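"""Gene lists and list-overlap statistics.

A :class:`GeneList` is a named, ordered, de-duplicated collection of
uppercase gene symbols — the container for disease seed lists such as a
set of atopy-associated genes or the causal genes of monogenic primary
immunodeficiencies.  :func:`overlap_stats` computes the set arithmetic
behind a Venn comparison of two such lists, reporting the intersection
relative to the union and to either list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ValidationError

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (0.25 -> 0.3 at 1 digit).

    Display percentages use half-up rounding so e.g. 15/160 reports as
    9.4%, matching how such figures are conventionally printed.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _normalize_symbols(symbols: Iterable[str]) -> tuple[str, ...]:
    """Uppercase, strip, drop blanks and duplicates (first kept)."""
    seen: dict[str, None] = {}
    for raw in symbols:
        sym = str(raw).strip().upper()
        if not sym:
            continue
        seen.setdefault(sym, None)
    return tuple(seen)


@dataclass(frozen=True)
class GeneList:
    """Named, ordered, de-duplicated list of uppercase gene symbols.

    Symbols are case-normalized at construction because human and mouse
    symbol casing differs (FLG vs Flg) and seed lists curated on human
    genes are routinely mapped onto mouse expression data.
    """

    name: str
    symbols: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        normalized = _normalize_symbols(self.symbols)
        n_dropped = len(tuple(self.symbols)) - len(normalized)
        if n_dropped:
            logger.info(
                "GeneList %r: dropped %d duplicate/blank symbols", self.name, n_dropped
            )
        object.__setattr__(self, "symbols", normalized)
        if not self.symbols:
            raise ValidationError(f"gene list {self.name!r} is empty after filtering")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: object) -> bool:
        return str(symbol).strip().upper() in set(self.symbols)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.symbols)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a plain-text gene list: one symbol per line, ``#`` comments.

    Parameters
    ----------
    path
        Text file with one gene symbol per line.  Blank lines and lines
        starting with ``#`` are ignored.
    name
        Label for the list; defaults to the file stem.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValidationError
        If no symbols remain after filtering.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    symbols = [ln for ln in (l.strip() for l in lines) if ln and not ln.startswith("#")]
    return GeneList(name=name or path.stem, symbols=tuple(symbols), source=str(path))


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    """Write one symbol per line, with a provenance comment header."""
    path = Path(path)
    header = f"# {genes.name}" + (f" — {genes.source}" if genes.source else "")
    path.write_text(header + "\n" + "\n".join(genes.symbols) + "\n")


@dataclass(frozen=True)
class OverlapStats:
    """Set-overlap statistics for two gene lists.

    ``pct_*`` fields are half-up rounded to one decimal for display; the
    unrounded values are kept in ``raw_pct_*``.
    """

    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    pct_of_union: float
    pct_of_a: float
    pct_of_b: float
    shared_symbols: tuple[str, ...]
    raw_pct_of_union: float = field(repr=False, default=0.0)
    raw_pct_of_a: float = field(repr=False, default=0.0)
    raw_pct_of_b: float = field(repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.n_union != self.n_a + self.n_b - self.n_intersection:
            raise ValidationError("union identity violated")
        if not 0 <= self.n_intersection <= min(self.n_a, self.n_b):
            raise ValidationError("intersection size out of range")


def overlap_stats(a: GeneList, b: GeneList) -> OverlapStats:
    """Exact overlap arithmetic between two gene lists.

    The headline percentage is the intersection over the *union* of the
    two lists; the percentages relative to each list are also reported
    so no information is lost.
    """
    sa, sb = a.as_set(), b.as_set()
    shared = sorted(sa & sb)
    n_i = len(shared)
    n_union = len(sa | sb)
    raw_u = 100.0 * n_i / n_union
    raw_a = 100.0 * n_i / len(sa)
    raw_b = 100.0 * n_i / len(sb)
    return OverlapStats(
        n_a=len(sa),
        n_b=len(sb),
        n_intersection=n_i,
        n_union=n_union,
        pct_of_union=round_half_up(raw_u),
        pct_of_a=round_half_up(raw_a),
        pct_of_b=round_half_up(raw_b),
        shared_symbols=tuple(shared),
        raw_pct_of_union=raw_u,
        raw_pct_of_a=raw_a,
        raw_pct_of_b=raw_b,
    )


def write_overlap_report(stats: OverlapStats, path: str | Path) -> None:
    """Overlap report as a two-column TSV, one row per statistic."""
    rows = [
        ("n_a", stats.n_a),
        ("n_b", stats.n_b),
        ("n_intersection", stats.n_intersection),
        ("n_union", stats.n_union),
        ("pct_of_union", stats.pct_of_union),
        ("pct_of_a", stats.pct_of_a),
        ("pct_of_b", stats.pct_of_b),
        ("shared_symbols", ",".join(stats.shared_symbols)),
    ]
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in rows))
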
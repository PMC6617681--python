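"""Gene-set over-representation scoring with one-sided Fisher's exact test.

For a query gene list and a collection of gene sets over a background
universe, each set is scored by the 2×2 table (in-query × in-set): the
one-sided (greater) Fisher exact p-value is the probability that at
least the observed number of query genes lands in the set by chance
alone.  Sets are ranked by p, and a set is flagged significant when
−log10(p) ≥ 1.3, i.e. p ≤ 0.05.  Benjamini–Hochberg q-values are
reported alongside for modern practice, but the significance flag
follows the raw-p rule.

The background universe matters: it defaults to the union of all set
members plus the query, and can (and usually should) be supplied
explicitly, e.g. all genes measured on the platform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import ParseError, ValidationError
from .genelists import GeneList

logger = logging.getLogger(__name__)

DEFAULT_NEGLOGP_THRESHOLD = 1.3


def _norm(symbols: Iterable[str]) -> frozenset[str]:
    return frozenset(s.strip().upper() for s in symbols if str(s).strip())


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over an explicit background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        normed = {name: _norm(members) for name, members in sets.items()}
        if universe is None:
            uni = frozenset().union(*normed.values()) if normed else frozenset()
        else:
            uni = _norm(universe)
            normed = {name: members & uni for name, members in normed.items()}
            normed = {name: m for name, m in normed.items() if m}
        return cls(sets=normed, universe=uni)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated ``name<TAB>description<TAB>genes…``."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {i}: GMT needs >= 3 tab-separated fields")
        name = fields[0].strip()
        if name in sets:
            raise ParseError(f"{path}: line {i}: duplicate set name {name!r}")
        members = _norm(fields[2:])
        if not members:
            raise ParseError(f"{path}: line {i}: set {name!r} has no genes")
        sets[name] = members
    return GeneSetCollection.from_sets(sets)


def write_gmt(
    collection: GeneSetCollection,
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def fisher_pvalue(n_hits: int, n_query: int, set_size: int, n_universe: int) -> float:
    """One-sided (greater) Fisher exact p for the 2×2 in-query × in-set
    table over a universe of *n_universe* genes."""
    table = [
        [n_hits, n_query - n_hits],
        [set_size - n_hits, n_universe - set_size - (n_query - n_hits)],
    ]
    if min(table[0] + table[1]) < 0:
        raise ValidationError("inconsistent 2x2 table")
    _, p = fisher_exact(table, alternative="greater")
    return float(min(max(p, 0.0), 1.0))


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_hits: int
    set_size: int
    ratio: float
    p_value: float
    q_value: float
    neg_log10_p: float
    significant: bool
    rank: int


def fisher_enrichment(
    query: GeneList | Iterable[str],
    collection: GeneSetCollection,
    threshold: float = DEFAULT_NEGLOGP_THRESHOLD,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Score each gene set for over-representation of the query.

    The query is restricted to the universe before testing (dropped
    symbols are logged).  Results are sorted by ascending p, ties by
    descending ratio then set name, and ranked from 1.
    """
    uni = _norm(universe) if universe is not None else collection.universe
    if not uni:
        raise ValidationError("empty background universe")
    query_syms = _norm(query)
    q = query_syms & uni
    dropped = len(query_syms) - len(q)
    if dropped:
        logger.info("fisher_enrichment: %d query symbols outside universe dropped",
                    dropped)
    if not q:
        raise ValidationError("query has no symbols inside the universe")
    U, Q = len(uni), len(q)
    rows = []
    for name, members in collection.sets.items():
        s = members & uni
        if not s:
            continue
        S = len(s)
        hits = len(q & s)
        p = fisher_pvalue(hits, Q, S, U)
        rows.append((name, hits, S, hits / S, p))
    if not rows:
        raise ValidationError("no gene set intersects the universe")
    pvals = [r[4] for r in rows]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    p_cut = 10.0 ** (-threshold)
    results = [
        EnrichmentResult(
            set_name=name,
            n_hits=hits,
            set_size=size,
            ratio=ratio,
            p_value=p,
            q_value=float(qv),
            neg_log10_p=-math.log10(p) if p > 0 else math.inf,
            significant=p <= p_cut,
            rank=0,
        )
        for (name, hits, size, ratio, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, -r.ratio, r.set_name))
    return [replace(r, rank=i) for i, r in enumerate(results, start=1)]


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                r.rank, r.set_name, r.n_hits, r.set_size, f"{r.ratio:.4f}",
                f"{r.p_value:.4g}", f"{r.q_value:.4g}", f"{r.neg_log10_p:.3f}",
                r.significant,
            )
            for r in results
        ],
        columns=[
            "rank", "set", "hits", "set_size", "ratio", "p", "q",
            "neg_log10_p", "significant",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
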
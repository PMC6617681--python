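"""Shared fixtures: hand-built toy matrices and the default synthetic
dataset (generated once per session — the analysis is deterministic)."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import seedclust as sc
from seedclust.expression import ExpressionMatrix


@pytest.fixture(scope="session")
def noiseless():
    """Default planted structure at zero noise, seed 1."""
    spec = sc.SyntheticSpec(noise_sd=0.0, seed=1)
    matrix, seeds, truth = sc.generate(spec)
    return spec, matrix, seeds, truth


@pytest.fixture(scope="session")
def noiseless_run(noiseless):
    spec, matrix, seeds, truth = noiseless
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant background rows at sd=0
        result = sc.run(matrix, seeds, sc.RunConfig(), truth=truth)
    return spec, matrix, seeds, truth, result


@pytest.fixture
def tiny_matrix():
    """5 probes × 6 samples with exact relationships: P2 = 2·P1 (perfectly
    correlated on raw and log2 surfaces), P3 is P1 mirrored around its
    mean, P4 independent, P5 constant."""
    p1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    values = pd.DataFrame(
        np.column_stack([p1, 2 * p1, 7.0 - p1, [4, 1, 5, 2, 6, 3], [2.0] * 6]).T,
        index=["P1", "P2", "P3", "P4", "P5"],
        columns=[f"s{i}" for i in range(6)],
    )
    genes = {"P1": "GA", "P2": "GB", "P3": "GC", "P4": "GD", "P5": "GE"}
    groups = {f"s{i}": "g1" if i < 3 else "g2" for i in range(6)}
    return ExpressionMatrix(values, genes, groups)


def naive_pearson(x, y):
    """Textbook Pearson correlation, element by element."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    if sx == 0 or sy == 0:
        return 0.0
    return sxy / (sx * sy)


def hypergeom_tail(n_hits, n_query, set_size, n_universe):
    """P(X >= n_hits) for X ~ Hypergeom(U, S, Q), by direct summation."""
    total = math.comb(n_universe, n_query)
    acc = 0
    for k in range(n_hits, min(set_size, n_query) + 1):
        acc += math.comb(set_size, k) * math.comb(n_universe - set_size, n_query - k)
    return acc / total
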
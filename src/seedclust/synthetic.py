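"""Synthetic expression data with planted co-expression structure.

The generator emulates an immune-compendium microarray design: samples
grouped into cell-lineage populations (default 12), probes whose log2
intensities follow a per-gene baseline plus a sparse lineage-activation
pattern plus Gaussian noise.  Seed genes are planted into co-expression
blocks:

* ``n_clusters`` seed clusters (default 11, sized so that 7 have ≥5
  seeds), each sharing a lineage-activation pattern with a block of
  companion genes large enough to saturate the top-K neighborhoods;
* one anti-correlated cluster pair whose two patterns are v and −v,
  giving opposite expression profiles;
* ``n_bins`` seeds with unique activation patterns and private
  companion blocks, so their neighborhoods are real but share no gene
  with any other seed's neighborhood;
* ``n_absent`` seeds that appear in the seed list but not the matrix
  ("not expressed");
* a pool of pure-noise background genes, and a few seeds carrying two
  probes (multiple transcripts).

Activation patterns are rejection-sampled so every pattern pair except
the planted anti-correlated one has |Pearson r| < the network edge
threshold; at zero noise the pipeline therefore provably recovers the
planted clusters, bins, and the unique anti-correlated pair.  All
randomness flows from a single integer seed through per-component
substreams, so the truth is stable when only downstream options change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import ExpressionMatrix
from .genelists import GeneList
from .enrichment import GeneSetCollection

ABSENT_LABEL = "absent"
BIN_PREFIX = "bin"

# default planted cluster sizes: 108 clustered seeds, seven clusters of
# >= 5 seeds and four smaller ones
DEFAULT_CLUSTER_SIZES = (22, 20, 17, 13, 10, 9, 7, 3, 3, 2, 2)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults describe a realistic desk-scale immune compendium: 12
    lineage groups × 12 samples, 160 seeds (108 clustered in 11
    clusters, 37 bins, 15 absent), top-K-saturating companion blocks,
    log2-scale Gaussian noise of 0.5 SD.
    """

    n_groups: int = 12
    samples_per_group: int = 12
    n_clusters: int = 11
    cluster_sizes: tuple[int, ...] = DEFAULT_CLUSTER_SIZES
    companions_per_cluster: int = 40
    n_bins: int = 37
    n_absent: int = 15
    n_background: int = 2000
    n_extra_probes: int = 8
    noise_sd: float = 0.5
    activation_amplitude: float = 3.0
    min_active_groups: int = 2
    max_active_groups: int = 4
    anticorrelated_pair: tuple[int, int] = (3, 5)
    baseline_log2: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValidationError("cluster_sizes length must equal n_clusters")
        if any(s < 2 for s in self.cluster_sizes):
            raise ValidationError("planted clusters need >= 2 seeds each")
        counts = (self.n_bins, self.n_absent, self.n_background,
                  self.n_extra_probes, self.companions_per_cluster)
        if any(c < 0 for c in counts) or self.noise_sd < 0:
            raise ValidationError("counts and noise_sd must be non-negative")
        a, b = self.anticorrelated_pair
        if a == b or not (0 <= a < self.n_clusters and 0 <= b < self.n_clusters):
            raise ValidationError("anticorrelated_pair must be two distinct cluster indices")
        if not 1 <= self.min_active_groups <= self.max_active_groups < self.n_groups:
            raise ValidationError("active-group range invalid")

    @property
    def n_seeds(self) -> int:
        return sum(self.cluster_sizes) + self.n_bins + self.n_absent

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.samples_per_group


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth recorded alongside the generated data."""

    assignment: dict[str, str]  # seed symbol -> cluster_## | bin | absent
    companion_map: dict[str, tuple[str, ...]]  # block key -> companion genes
    group_patterns: dict[str, tuple[float, ...]]  # block key -> activation
    background_genes: tuple[str, ...]
    anticorrelated_pair: tuple[str, str]

    def cluster_keys(self) -> list[str]:
        return sorted(k for k in self.group_patterns if k.startswith("cluster_"))

    def seeds_of(self, key: str) -> tuple[str, ...]:
        return tuple(
            sorted(g for g, lab in self.assignment.items() if lab == key)
        )

    def probe_truth_labels(
        self, probes: Iterable[str], probe_to_gene: dict[str, str]
    ) -> dict[str, str]:
        """Truth label per probe; each bin gene gets its own label so a
        partition comparison treats bins as singletons."""
        out = {}
        for p in probes:
            gene = probe_to_gene[p]
            lab = self.assignment.get(gene)
            if lab is None or lab == ABSENT_LABEL:
                continue
            out[p] = f"bin::{gene}" if lab == BIN_PREFIX else lab
        return out


def _sample_pattern(
    rng: np.random.Generator, spec: SyntheticSpec, existing: list[np.ndarray],
    max_abs_corr: float = 0.65, max_tries: int = 10000,
) -> np.ndarray:
    """Sparse activation vector with |corr| < max_abs_corr vs existing."""
    for _ in range(max_tries):
        k = int(rng.integers(spec.min_active_groups, spec.max_active_groups + 1))
        groups = rng.choice(spec.n_groups, size=k, replace=False)
        v = np.zeros(spec.n_groups)
        v[groups] = spec.activation_amplitude
        if all(abs(_pattern_corr(v, w)) < max_abs_corr for w in existing):
            return v
    raise ValidationError("could not sample a sufficiently distinct pattern")


def _pattern_corr(v: np.ndarray, w: np.ndarray) -> float:
    vc, wc = v - v.mean(), w - w.mean()
    d = np.linalg.norm(vc) * np.linalg.norm(wc)
    return float(vc @ wc / d) if d > 0 else 0.0


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GeneList, SyntheticTruth]:
    """Generate (matrix, seed list, truth) from a :class:`SyntheticSpec`.

    Intensities are ``2 ** (baseline + activation[group] + N(0, sd²))``,
    hence strictly positive.  Reproducible: the same spec (including
    its seed) yields bit-identical output.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_pat, rng_assign, rng_noise, rng_base = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # --- seed symbols, shuffled so symbol order does not encode truth
    seeds = [f"SEED{i + 1:04d}" for i in range(spec.n_seeds)]
    order = rng_assign.permutation(spec.n_seeds)
    shuffled = [seeds[i] for i in order]
    assignment: dict[str, str] = {}
    pos = 0
    cluster_members: dict[str, list[str]] = {}
    for c, size in enumerate(spec.cluster_sizes):
        key = f"cluster_{c:02d}"
        members = shuffled[pos : pos + size]
        pos += size
        cluster_members[key] = members
        assignment.update({g: key for g in members})
    bin_genes = shuffled[pos : pos + spec.n_bins]
    pos += spec.n_bins
    assignment.update({g: BIN_PREFIX for g in bin_genes})
    absent_genes = shuffled[pos:]
    assignment.update({g: ABSENT_LABEL for g in absent_genes})

    # --- activation patterns (anti-correlated pair is v and -v)
    a_idx, b_idx = spec.anticorrelated_pair
    patterns: dict[str, np.ndarray] = {}
    accepted: list[np.ndarray] = []
    for c in range(spec.n_clusters):
        key = f"cluster_{c:02d}"
        if c == b_idx:
            continue  # filled from its partner below
        v = _sample_pattern(rng_pat, spec, accepted)
        patterns[key] = v
        accepted.append(v)
        if c == a_idx:
            w = -v
            patterns[f"cluster_{b_idx:02d}"] = w
            accepted.append(w)
    for i, g in enumerate(bin_genes):
        key = f"{BIN_PREFIX}_{i:02d}"
        v = _sample_pattern(rng_pat, spec, accepted)
        patterns[key] = v
        accepted.append(v)

    # --- companions: one block per cluster, one private block per bin
    companion_map: dict[str, tuple[str, ...]] = {}
    block_of_gene: dict[str, str] = {}
    for c in range(spec.n_clusters):
        key = f"cluster_{c:02d}"
        comps = tuple(
            f"C{c:02d}G{j + 1:03d}" for j in range(spec.companions_per_cluster)
        )
        companion_map[key] = comps
        for g in comps:
            block_of_gene[g] = key
        for g in cluster_members[key]:
            block_of_gene[g] = key
    for i, g in enumerate(bin_genes):
        key = f"{BIN_PREFIX}_{i:02d}"
        comps = tuple(
            f"B{i:02d}G{j + 1:03d}" for j in range(spec.companions_per_cluster)
        )
        companion_map[key] = comps
        for cg in comps:
            block_of_gene[cg] = key
        block_of_gene[g] = key

    background = tuple(f"BG{j + 1:05d}" for j in range(spec.n_background))

    # --- probes: one per present gene, plus extras on clustered seeds
    present_genes = (
        [g for ms in cluster_members.values() for g in ms]
        + bin_genes
        + [g for comps in companion_map.values() for g in comps]
        + list(background)
    )
    probes: list[tuple[str, str]] = [(f"{g}_at", g) for g in present_genes]
    clustered_seeds = [g for ms in cluster_members.values() for g in ms]
    if spec.n_extra_probes > len(clustered_seeds):
        raise ValidationError("n_extra_probes exceeds number of clustered seeds")
    extra = rng_assign.choice(
        len(clustered_seeds), size=spec.n_extra_probes, replace=False
    )
    for i in sorted(extra):
        g = clustered_seeds[i]
        probes.append((f"{g}_x_at", g))

    # --- samples and groups
    sample_ids = []
    sample_to_group = {}
    for g in range(spec.n_groups):
        group = f"G{g + 1:02d}"
        for r in range(spec.samples_per_group):
            sid = f"{group}S{r + 1:02d}"
            sample_ids.append(sid)
            sample_to_group[sid] = group
    group_idx = np.repeat(np.arange(spec.n_groups), spec.samples_per_group)

    # --- assemble log2 matrix
    n_probes, n_samples = len(probes), len(sample_ids)
    log2 = np.empty((n_probes, n_samples))
    baselines = spec.baseline_log2 + rng_base.uniform(-1.0, 1.0, size=n_probes)
    for i, (probe, gene) in enumerate(probes):
        block = block_of_gene.get(gene)
        act = patterns[block][group_idx] if block is not None else 0.0
        log2[i] = baselines[i] + act
    if spec.noise_sd > 0:
        log2 += rng_noise.normal(0.0, spec.noise_sd, size=log2.shape)

    values = pd.DataFrame(
        np.power(2.0, log2), index=[p for p, _ in probes], columns=sample_ids
    )
    matrix = ExpressionMatrix(
        values=values,
        probe_to_gene={p: g for p, g in probes},
        sample_to_group=sample_to_group,
    )
    seed_list = GeneList(
        name="synthetic_seeds", symbols=tuple(seeds), source="planted generator"
    )
    truth = SyntheticTruth(
        assignment=assignment,
        companion_map=companion_map,
        group_patterns={k: tuple(v) for k, v in patterns.items()},
        background_genes=background,
        anticorrelated_pair=(f"cluster_{a_idx:02d}", f"cluster_{b_idx:02d}"),
    )
    return matrix, seed_list, truth


def generate_genesets(
    truth: SyntheticTruth, n_decoys: int, seed: int = 0
) -> GeneSetCollection:
    """Gene-set collection: one set per planted cluster (its seeds plus
    companions) and ``n_decoys`` random background sets of matched sizes."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    sets: dict[str, frozenset[str]] = {}
    sizes = []
    for key in truth.cluster_keys():
        members = frozenset(truth.seeds_of(key)) | frozenset(truth.companion_map[key])
        sets[f"{key}_module"] = members
        sizes.append(len(members))
    bg = np.asarray(truth.background_genes, dtype=object)
    if n_decoys and len(bg) == 0:
        raise ValidationError("no background genes available for decoys")
    for d in range(n_decoys):
        size = min(sizes[d % len(sizes)], len(bg)) if sizes else min(40, len(bg))
        pick = rng.choice(len(bg), size=size, replace=False)
        sets[f"decoy_{d:03d}"] = frozenset(str(bg[i]) for i in pick)
    return GeneSetCollection.from_sets(sets)


# the 22 overlapping atopy/PID symbols reported in the source study;
# used as the shared block of the demo list builder
_SHARED_DEMO_SYMBOLS = (
    "ARPC1B", "BTK", "CASP8", "CFTR", "CTLA4", "DOCK8", "ICOS", "IL10",
    "IL12B", "IL12RB1", "IL17F", "IL21", "IL21R", "IL7R", "ITK", "ORAI1",
    "PGM3", "SPINK5", "STAT3", "TNFRSF13B", "TRAF3IP2", "TYK2",
)


def demo_overlap_lists(
    n_a: int = 160, n_b: int = 278, n_shared: int = 22
) -> tuple[GeneList, GeneList]:
    """Two gene lists with a fixed overlap, for overlap-statistics demos.

    Defaults reproduce the study-scale comparison: a 160-gene
    atopy-style list vs a 278-gene immunodeficiency-style list sharing
    22 symbols.  The shared block uses the reported shared symbols
    (padded/truncated to *n_shared*); fillers are generated.
    """
    if n_shared > min(n_a, n_b):
        raise ValidationError("n_shared exceeds a list size")
    shared = list(_SHARED_DEMO_SYMBOLS[:n_shared])
    shared += [f"SHR{i:04d}" for i in range(max(0, n_shared - len(shared)))]
    a = shared + [f"ATOPY{i + 1:04d}" for i in range(n_a - n_shared)]
    b = shared + [f"PID{i + 1:04d}" for i in range(n_b - n_shared)]
    return (
        GeneList("list_a", tuple(a), source="demo"),
        GeneList("list_b", tuple(b), source="demo"),
    )
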
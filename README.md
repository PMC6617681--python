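# seedclust

Co-expression neighborhood clustering of disease seed genes across
immune cell lineages.

## The problem

Clinically heterogeneous diseases such as the atopic syndrome (atopic
dermatitis, food allergy, asthma, allergic rhinitis) are driven by many
associated genes.  Subsets of those genes that are co-expressed across
immune cell lineages plausibly act in the same molecular pathway and
point to mechanistic disease subclasses (endotypes).  `seedclust` takes
a curated list of disease-associated "seed" genes and an expression
compendium of immune cell populations, and groups the seeds by the
overlap of their co-expression neighborhoods.

## The method

For each seed probe *i* (seeds absent from the compendium are reported
as not expressed and excluded), the top *K* = 40 probes by Pearson
correlation of log2 intensities form its co-expression neighborhood
N(i).  Two seeds are connected in the seed network when

* |N(i) ∩ N(j)| ≥ 1, counted on gene symbols, and
* r(i, j) ≥ 0.65, the Pearson correlation of their expression profiles,

and clusters are the connected components of that graph.  A seed whose
neighborhood shares no gene with any other seed's is an unclustered
"bin" gene; clusters with ≥ 5 members are the named clusters.  Cluster
mean profiles are compared pairwise and pairs with r ≤ −0.65 are
flagged as anti-correlated (opposite expression programs).  For
display, each probe row is expressed as log2 deviations from its
geometric mean, so rows sum to zero and red/blue encode expression
above/below the probe's typical level.

Two supporting analyses round out the pipeline: exact overlap
statistics between two gene lists (intersection over union and per
list), and gene-set over-representation of the seed list scored with a
one-sided Fisher exact test over an explicit background universe, with
sets flagged significant at −log10 p ≥ 1.3 (p ≤ 0.05) and
Benjamini–Hochberg q-values reported alongside.

Because real compendia and curated disease lists require external
resources, the package ships a planted-structure simulator
(`seedclust.synthetic`) that generates expression matrices with known
cluster/bin/absent assignments, an anti-correlated cluster pair,
multi-transcript probes, and matched gene-set collections — every
pipeline stage is testable offline against recorded ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a
simulated compendium (4073 probes × 144 samples, 12 lineage groups,
160 seeds, log2 noise SD 0.5):

```bash
python analysis/01_simulate_compendium.py   # writes results/synthetic/
python analysis/02_list_overlap.py
python analysis/03_cluster_seed_genes.py
python analysis/04_expression_heatmap.py
python analysis/05_pathway_enrichment.py
python analysis/06_noise_robustness.py
```

Step 02 prints the list comparison:

```
lists: |A| = 160, |B| = 278, union 416
22 genes overlap: 5.3% of the union (13.8% of A, 7.9% of B)
```

Step 03 prints the clustering result and its agreement with the
planted truth:

```
160 seeds: 145 expressed on 153 probes, 15 absent (9.4%)
11 clusters (7 with >= 5 members), 37 bin genes, 890 network edges
anti-correlated cluster pairs: [['D', 'E']]
adjusted Rand index vs planted truth: 1.000
```

i.e. 15 of the 160 seeds are not expressed in the compendium; the 145
expressed seeds map to 153 probes (some genes have multiple
transcripts); the pipeline recovers all 11 planted clusters, the 37 bin
genes, and flags exactly the one planted anti-correlated cluster pair —
an adjusted Rand index of 1.0 against the simulation truth.  Step 05
tests the seed list against 11 planted cluster modules plus 100 random
decoy sets:

```
111 sets tested against a universe of 4065 genes
7 significant at -log10 p >= 1.3 (0 of them decoys)
  rank 1: cluster_00_module hits=22/62 ratio=0.35 -log10p=16.5
```

— the seven large planted modules are flagged and no decoy is.  Step 06
shows recovery degrading gracefully with noise (mean ARI 1.0 up to
SD 0.5, ≈ 0.8 at SD 1.0).

The same stages are available as a CLI (`seedclust simulate | overlap |
cluster | heatmap | enrich | run-all`) for user-supplied data:
TSV/CSV expression tables (a GEO series-matrix reader is included),
plain-text gene lists, and GMT gene sets.

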
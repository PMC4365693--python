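# cyanocore

Comparative pan-genome analysis for phylum-scale bacterial studies, built
around the kind of multi-genome survey done for cyanobacteria: dozens of
sequenced strains, an ortholog-cluster table from a tool such as OrthoMCL,
curated phenotype annotations, and the question of what is universally
shared, what is clade- or lifestyle-specific, and how the outer-membrane
proteome is distributed across the phylum.

The package is aimed at comparative genomicists who already have ortholog
clusters, alignments, homology-search tables and predictor outputs, and want
a reproducible, testable implementation of the downstream analysis.

## What it computes

**Core/pan-genome structure.** The unit of analysis is the CLOG (CLique of
Orthologous Genes): an ortholog cluster with sequences from one or more
genomes. Over a universe of *G* genomes, a CLOG is *core* if every genome
contributes at least one sequence, *unique* if a single genome contributes
all of them (including multi-sequence putative paralog families), and
*dispensable* otherwise. Rarefaction repeatedly draws random genome subsets
of every size *n* and tracks core(*n*) and pan(*n*). The growth of the
pan-genome is summarized by the Tettelin-style power law for the mean number
of new CLOGs contributed by the *n*-th genome,

    new(n) = kappa * n^(-alpha),

fitted by least squares on log new(n) vs log n, with a bootstrap spread over
the per-step replicates. Only alpha > 1 implies a finite pan-genome; smaller
exponents mean an *open* pan-genome that keeps growing as strains are added.

**Phenotype similarity.** Strains are described by features (habitat,
morphology, nitrogen fixation, ...) encoded as bit strings over
subcategories, with an explicit `unknown` state. The Tanimoto-like index
accumulates |x AND y| into the numerator and |x OR y| into the denominator
per feature; a feature unknown in both strains is skipped, and a feature
known in exactly one strain adds 0.5 to the denominator only. With no
unknowns this is the classical Tanimoto/Jaccard coefficient.

**Trees and their comparison.** Saitou–Nei neighbor joining is applied to
any distance matrix: 1 − CLOG-sharing similarity (the Jaccard index of two
strains' CLOG sets), 1 − feature similarity, 1 − AAI (mean global-alignment
identity over single-copy core CLOGs), or p-distances from a 16S-style
alignment. Trees are compared by the Pearson correlation of their patristic
(path-length) distances over shared leaves.

**Signature genes.** Feature-specific CLOGs contain sequences exclusively
from strains positive for a phenotype, either covering all positives
(exact) or bucketed by support (relaxed). Candidates are promoted to
signature genes when a homology search against outgroup genomes yields no
hit with ≥ 80% bait coverage and e-value ≤ 1e-10.

**β-barrel outer-membrane proteins.** Each protein is scored by two major
criteria (≥ 2 sequence-predictor votes; ≥ 1 profile-HMM β-barrel family hit)
and two minor criteria (an uncovered stretch longer than 79 residues outside
non-barrel Pfam domains; a strict-majority vote of both majors within its
CLOG), then placed in category (a) all four, (b) majors + one minor,
(c) majors only with structural confirmation, or (d) everything else.

**Functional profiles.** COG category letters are aggregated per gene set
(dual-annotated genes count once per category; > 2 categories collapse to
X), and incremental profiles along nested clade chains show which functions
enter at the phylum-wide core versus clade-specific cores.

All stages are also covered by a synthetic-data module that generates every
input with known ground truth (planted pan-genome composition,
clade-structured feature tables, proteins evolved along a known tree,
predictor evidence at stated sensitivity/specificity).

## Worked example

The end-to-end demo generates a 12-genome synthetic study — 80 core CLOGs,
300 dispensable CLOGs, ~25 unique CLOGs per genome, 4 planted
thermophile-exclusive CLOGs with superset/subset decoys, a two-clade feature
table, and β-barrel evidence — then runs the full analysis:

```sh
cyanocore demo --seed 1
```

```json
{
  "classify": {"core": 80, "dispensable": 308, "unique": 285},
  "accumulation": {
    "core_mean_at_G": 80.0,
    "alpha": 0.7070302493983956,
    "alpha_sd": 0.0070780620794320195,
    "open_pangenome": true
  },
  "feature_tree": {"patristic_correlation_vs_clog_tree": -0.05419124873997956},
  "signatures": {"exact_clogs": 4},
  "barrels": {"a": 34, "d": 85, "b": 1}
}
```

Reading this: classification recovers the planted 80 core CLOGs exactly (the
308 dispensable include the planted signature CLOGs and their decoys, which
occupy 2–5 genomes each); the new-genes curve fits an exponent alpha ≈ 0.71
< 1, an open pan-genome; exact feature mining finds precisely the 4 planted
thermophile CLOGs and no decoys; the barrel consensus assigns most true
barrels to category (a) and the rest of the proteins to (d). The feature
tree is uncorrelated with the CLOG tree here because the demo's gene content
carries no clade structure — only the feature table does.

Individual stages are available as subcommands (`classify`, `rarefy`,
`fit-alpha`, `feature-dist`, `nj`, `tree-corr`, `aai`, `signatures`,
`barrels`, `clade-profile`, `simulate`) operating on the plain-text formats
described in the module docstrings, or directly as library functions.

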
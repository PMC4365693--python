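# Methods

This note documents the models and procedures implemented in `cyanocore`,
the conventions chosen where several were defensible, and what the synthetic
data do and do not establish about behaviour on real data.

## CLOG classification

A CLOG table maps cluster ids to (genome, gene) members over an explicit
genome universe. Classification is purely set-based: *core* iff the member
genomes equal the universe, *unique* iff they are a single genome,
*dispensable* otherwise. Two conventions matter:

- **Unique is genome-level, not sequence-level.** A cluster with five
  sequences from one strain is a unique-gene CLOG (putative paralog family),
  unified with unclustered singletons. `multi_sequence_unique_clogs`
  separates the multi-sequence families when needed.
- **The universe is explicit.** Core calls depend on what "all strains"
  means; the genome registry, not the cluster file, defines it. A genome
  with no clustered genes still blocks core calls.

Upstream sequence QC mirrors common pre-clustering filters: sequences
shorter than 10 residues or with a stop-codon (`*`) frequency strictly above
20% fail; the CDS:protein check accepts both 3L and 3(L+1) nucleotides
because the stop codon may or may not be included in the CDS — both
encodings are biologically valid, anything else indicates mis-annotation.
Ambiguity codes are ordinary residues; only `*` counts as a stop.

## Rarefaction and the power-law exponent

`rarefy` draws, for each subset size n in 1..G, R uniform subsets without
replacement (default R = 1000 for study-scale runs; tests and the demo use
100–500) and records core(n)/pan(n) replicates; five-number summaries
support box-plot style reporting because the raw replicates are kept. A
`nested` mode samples one random ordering per replicate and uses its
prefixes, making per-replicate monotonicity (core non-increasing, pan
non-decreasing) exact. An `exhaustive` mode enumerates every subset once,
used by tests as an exact oracle for small G.

The openness exponent is fitted on the *new-genes-per-genome* curve, not on
pan-genome size: new(n) = pan(first n) − pan(first n−1) over random
orderings, mean-aggregated per step, then least squares on
log mean new(n) vs log n for n ≥ 2. This is the convention under which
"only alpha > 1 gives a finite pan-genome" is the correct openness
criterion. Means (not medians) are fitted by default; both the aggregation
and the n-range are arguments. The ± on alpha is a bootstrap over the
per-step replicate values (default 100 refits); non-positive means are
dropped with a record before taking logs, and fewer than three surviving
points is an error.

`core_ratio` compares a clade's observed core size with the mean core
rarefaction replicate at n = |clade|; ratios well above 1 indicate a clade
sharing far more genes than a random strain sample of its size.

## Tanimoto-like feature index

Per feature: unknown in both strains → skipped; known in exactly one →
denominator += 0.5; known in both → numerator += popcount(AND), denominator
+= popcount(OR). The 0.5 increment penalizes half-known comparisons without
asserting disagreement. A feature known and all-zero in both strains
contributes nothing to either side — this falls out of the rules and is
asserted in tests rather than special-cased. Pairs where every feature is
unknown in at least one strain have an undefined index; matrix construction
fails loudly unless `allow_missing` substitutes a configured maximal
distance (there is no principled imputation for such pairs, so the default
refuses to guess). Logical assumptions (e.g. unicellular strains cannot
form heterocysts) are applied only through an explicit inference-rule file
that fills unknown cells and logs every application.

## Trees

Neighbor joining is the classical Saitou–Nei agglomeration. Two details are
pinned down because downstream comparisons depend on them:

- **Determinism.** Ties in the Q criterion are broken by the
  lexicographically smallest pair of subtree representative labels, so a
  given matrix always yields the same tree.
- **Negative branches.** A negative estimated length is clamped to zero and
  the deficit moved to its sister branch, preserving the joined pair's
  mutual distance (standard practice; verified to preserve additivity on
  additive inputs). The implementation is cross-checked against scikit-bio's
  independent NJ on additive matrices in the test suite.

AAI between two strains is the mean Needleman–Wunsch global-alignment
identity over single-copy core CLOGs (core CLOGs with exactly one sequence
per genome). Scoring defaults: BLOSUM62, gap open 10, gap extend 0.5 —
common defaults, configurable, and logged; no specific scheme is canonical
for AAI. Identity uses all alignment columns (including gap columns) in the
denominator by default, with shorter-sequence and ungapped-column
conventions available. 16S-style distances are p-distances (mismatches over
compared columns, pairwise-deleting gap columns); a model-corrected distance
could be substituted upstream since any distance matrix feeds the same NJ.

Tree comparison is the Pearson correlation of patristic distances over the
shared leaf set (≥ 3 leaves required), computed on upper triangles. It is
symmetric and invariant to uniform branch scaling; zero-variance degenerate
cases raise rather than returning NaN.

## Signature mining

Strains with unknown phenotype status are excluded from the positive set —
feature-exclusive CLOGs are mined against confirmed positives only. Exact
mining requires the CLOG's genome set to *equal* the positive set; relaxed
mining requires it to be a *subset*, bucketed by support. The specificity
filter is inclusive at both boundaries (coverage ≥ 0.80 of the bait
sequence, e-value ≤ 1.0e-10) and reports qualifying outgroup hits both per
subject sequence and per distinct subject organism, since published counts
can follow either convention.

## β-barrel consensus

All three numeric readings are strict: "more than one predictor" = at least
2 votes; "more than 50% of a CLOG" = fraction strictly greater than 0.5
(2 of 4 members fails); "longer than 79 residues" = an uncovered run of at
least 80 after merging non-barrel Pfam intervals. The CLOG-vote denominator
counts *all* members of the cluster; members without evidence rows count as
non-passing. A protein in a CLOG that fails the vote keeps
`clog_detected = false` but can still reach category (b) through the Pfam
criterion — the four criteria are independent columns. Category (b) is
*exactly one* minor criterion. The family label is the best profile-HMM
hit (lowest e-value, ties by bit score then family name); this replaces
barrel-domain sequence clustering with a simpler, deterministic labeling.
Structural confirmation (category c) is an input flag supplied from
external structure prediction and inspection, not computed here.

## Functional profiles

Genes annotated with two COG categories count once in each; more than two
collapse to the synthetic letter X, which never co-counts with real
letters. Clade chains must be strictly nested, largest first; branching
inputs are rejected rather than linearized. Increment i is the
representative strain's genes in clade i's core minus all earlier (larger)
cores; the increments partition the smallest clade's core exactly, which is
asserted, not assumed. A category's profile is labeled *core-defined* if
more than 2/3 of its mass enters at the whole-universe step, *clade-defined*
if more than 2/3 enters at clade steps, otherwise *mixed*; the threshold is
an argument. This transparent rule replaces any distribution-fitting of the
profile shape.

## Synthetic data

Generators are pure functions of (spec, seed) and emit structures that are
validated against the consuming modules' invariants.

- **Pan-genome**: planted core, dispensable (occupancy drawn from a
  configurable spectrum, default weight ∝ occupancy⁻², mimicking the steeply
  decreasing occupancy histograms of real ortholog tables), per-genome
  Poisson unique counts, optional paralog injection, and planted
  feature-exclusive CLOGs with superset/subset decoys. Dispensable occupancy
  sets never collide with planted signature sets, so mining truth is exact.
- **Open-pangenome conditions**: `open_pangenome_spec()` (G = 20, 100 core,
  400 dispensable, 48 unique per genome) was calibrated once by pilot
  simulation so the fitted exponent sits near alpha = 0.35, the open-regime
  value typical of phylum-wide samples; recovery within ±0.05 is the
  acceptance check.
- **Features**: clades share fingerprints; cells are masked to unknown
  independently at the stated rate.
- **Proteins**: gap-free sequences evolve along a known tree; per-branch
  substitution probability 1 − exp(−b·rate), replacement uniform over the
  20-letter alphabet, so distant identity decays to the 1/20 baseline and
  global alignments have a known gap-free optimum. No indels, no rate
  heterogeneity.
- **Barrel evidence**: per-predictor votes at stated
  sensitivity/specificity around a known truth, label-homogeneous CLOGs,
  Pfam coverage tiled so the uncovered-run criterion is controlled.

**What passing on synthetics does not show**: real ortholog tables carry
correlated error (fragmented assemblies, split/merged clusters, annotation
artifacts inflating unique counts); real phenotype tables have structured,
non-independent missingness; real proteins have indels and among-site rate
variation, so AAI topology recovery on real data will degrade faster with
divergence than the gap-free simulation suggests; predictor errors on real
proteomes are correlated across predictors, which the independent-vote model
ignores. The synthetic results establish correctness of the computations,
not field performance of the upstream predictors.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately compact sizes chosen as
adequate for their statistical checks: 100–200 random tables for oracle
comparisons, 200 permutations / 20 seeds for exponent recovery, 100 seeds
for topology recovery, a few hundred proteins for the barrel truth table.
Tolerances: patristic round-trips at 1e-9 (float accumulation over ≤ 40
branches), closed-form exponent recovery at 1e-9, Monte-Carlo comparisons at
a few standard errors. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical outputs,
and the pipeline manifest records seeds, parameters and output checksums.
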
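"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its specification and seed, and the
structures it emits satisfy the invariants of the modules that consume them.
The pan-genome generator plants core, dispensable, unique and
feature-signature CLOGs with a configurable occupancy spectrum; the feature
generator produces clade-structured phenotype fingerprints with a stated
unknown rate; the protein generator evolves gap-free sequences along a known
tree; the β-barrel generator draws predictor votes at stated sensitivity and
specificity around a known barrel/non-barrel truth.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .clogs import ClogTable
from .barrels import BarrelEvidence, PhmmHit
from .features import FeatureTable

__all__ = [
    "SignatureSpec",
    "PanGenomeSpec",
    "EvolutionSpec",
    "BarrelSimSpec",
    "gen_pan_genome",
    "gen_feature_table",
    "gen_divergent_proteins",
    "gen_barrel_evidence",
    "random_tree",
    "random_clog_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def genome_ids(G: int) -> list[str]:
    return [f"G{i:02d}" for i in range(1, G + 1)]


# ---------------------------------------------------------------------------
# pan-genome
# ---------------------------------------------------------------------------

@dataclass
class SignatureSpec:
    """Planted feature-exclusive CLOGs plus decoys that must not be found."""

    feature_name: str
    members: frozenset[str]
    n_exact: int = 3
    n_superset_decoys: int = 2
    n_subset_decoys: int = 2


@dataclass
class PanGenomeSpec:
    """Study conditions for a synthetic pan-genome.

    ``dispensable_spectrum`` gives probability weights over occupancies
    2..G-1; the default weight ~ occupancy^-2 mimics the steeply decreasing
    occupancy histogram of real ortholog tables, where most dispensable
    clusters touch only a few strains.
    """

    G: int = 20
    core_count: int = 100
    dispensable_count: int = 400
    unique_rate: float = 30.0          # mean unique CLOGs per genome (Poisson)
    paralog_probability: float = 0.0   # extra within-genome copy per core slot
    dispensable_spectrum: Sequence[float] | None = None
    signatures: list[SignatureSpec] = field(default_factory=list)
    seed: int = 0

    def spectrum(self) -> np.ndarray:
        occ = np.arange(2, self.G)
        if self.dispensable_spectrum is None:
            w = occ.astype(float) ** -2.0
        else:
            w = np.asarray(self.dispensable_spectrum, dtype=float)
            if len(w) != len(occ):
                raise ValueError(
                    f"spectrum needs {len(occ)} weights for occupancies 2..{self.G - 1}"
                )
        return w / w.sum()

    def validate(self) -> None:
        if self.G < 2:
            raise ValueError("need at least two genomes")
        if min(self.core_count, self.dispensable_count) < 0 or self.unique_rate < 0:
            raise ValueError("counts must be non-negative")
        ids = set(genome_ids(self.G))
        for sig in self.signatures:
            if not sig.members <= ids:
                raise ValueError(
                    f"signature {sig.feature_name!r} references genomes outside 1..G"
                )
            if len(sig.members) < 1:
                raise ValueError("signature member set is empty")


def open_pangenome_spec(seed: int = 0) -> PanGenomeSpec:
    """Study conditions for an open synthetic pan-genome.

    Calibrated by pilot simulation (closed over the defaults below) so that
    the fitted new-genes power-law exponent sits near alpha = 0.35, the
    open-pangenome regime reported for phylum-wide cyanobacterial samples:
    20 genomes, 100 core CLOGs, 400 dispensable CLOGs with the occupancy^-2
    spectrum, and a mean of 48 unique CLOGs per genome.
    """
    return PanGenomeSpec(
        G=20, core_count=100, dispensable_count=400, unique_rate=48.0, seed=seed
    )


def gen_pan_genome(spec: PanGenomeSpec) -> tuple[ClogTable, dict[str, str]]:
    """Generate a ClogTable and per-CLOG truth labels.

    Truth labels: ``core`` / ``dispensable`` / ``unique`` /
    ``signature_exact:<feature>`` / ``decoy_superset:<feature>`` /
    ``decoy_subset:<feature>``.  Dispensable occupancy sets never collide
    with a planted signature member set, so exact-feature mining has an
    unambiguous truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = genome_ids(spec.G)
    clogs: dict[str, list[tuple[str, str]]] = {}
    truth: dict[str, str] = {}
    gene_no = 0

    def gene(g: str) -> str:
        nonlocal gene_no
        gene_no += 1
        return f"{g.lower()}_{gene_no:06d}"

    for i in range(spec.core_count):
        cid = f"CORE{i + 1:05d}"
        members = [(g, gene(g)) for g in ids]
        if spec.paralog_probability > 0:
            for g in ids:
                if rng.random() < spec.paralog_probability:
                    members.append((g, gene(g)))
        clogs[cid] = members
        truth[cid] = "core"

    forbidden = {sig.members for sig in spec.signatures}
    occ_values = np.arange(2, spec.G)
    probs = spec.spectrum()
    for i in range(spec.dispensable_count):
        cid = f"DISP{i + 1:05d}"
        while True:
            occ = int(rng.choice(occ_values, p=probs))
            chosen = frozenset(rng.choice(ids, size=occ, replace=False))
            if chosen not in forbidden:
                break
        clogs[cid] = [(g, gene(g)) for g in sorted(chosen)]
        truth[cid] = "dispensable"

    for g in ids:
        n_unique = int(rng.poisson(spec.unique_rate))
        for i in range(n_unique):
            cid = f"UNIQ_{g}_{i + 1:05d}"
            clogs[cid] = [(g, gene(g))]
            truth[cid] = "unique"

    for sig in spec.signatures:
        members = sorted(sig.members)
        for i in range(sig.n_exact):
            cid = f"SIG_{sig.feature_name}_{i + 1:03d}"
            clogs[cid] = [(g, gene(g)) for g in members]
            truth[cid] = f"signature_exact:{sig.feature_name}"
        outside = sorted(set(ids) - sig.members)
        for i in range(sig.n_superset_decoys):
            if not outside:
                break
            cid = f"DECOYSUP_{sig.feature_name}_{i + 1:03d}"
            extra = str(rng.choice(outside))
            clogs[cid] = [(g, gene(g)) for g in members + [extra]]
            truth[cid] = f"decoy_superset:{sig.feature_name}"
        for i in range(sig.n_subset_decoys):
            if len(members) < 2:
                break
            cid = f"DECOYSUB_{sig.feature_name}_{i + 1:03d}"
            drop = str(rng.choice(members))
            clogs[cid] = [(g, gene(g)) for g in members if g != drop]
            truth[cid] = f"decoy_subset:{sig.feature_name}"

    return ClogTable(clogs, genome_universe=ids), truth


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def gen_feature_table(
    clades: Mapping[str, Sequence[str]],
    features: Sequence[tuple[str, Sequence[str]]],
    unknown_rate: float = 0.1,
    seed: int = 0,
    fingerprints: Mapping[str, Mapping[str, frozenset]] | None = None,
) -> tuple[FeatureTable, dict]:
    """Clade-structured feature table with independent unknown masking.

    All genomes of a clade share the clade fingerprint (given explicitly or
    drawn with each subcategory present with probability 1/2); each cell is
    then masked to unknown independently with probability ``unknown_rate``.
    Truth records the clade assignment, fingerprints, and the mask.
    """
    if not 0 <= unknown_rate < 1:
        raise ValueError("unknown_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if fingerprints is None:
        fingerprints = {
            clade: {
                name: frozenset(s for s in subs if rng.random() < 0.5)
                for name, subs in features
            }
            for clade in clades
        }
    values: dict[str, dict[str, frozenset | None]] = {}
    mask: dict[tuple[str, str], bool] = {}
    assignment: dict[str, str] = {}
    for clade, genomes in clades.items():
        for g in genomes:
            assignment[g] = clade
            row: dict[str, frozenset | None] = {}
            for name, _ in features:
                hidden = bool(rng.random() < unknown_rate)
                mask[(g, name)] = hidden
                row[name] = None if hidden else fingerprints[clade][name]
            values[g] = row
    ft = FeatureTable(features, values)
    return ft, {"clades": assignment, "fingerprints": dict(fingerprints), "mask": mask}


# ---------------------------------------------------------------------------
# divergent proteins along a known tree
# ---------------------------------------------------------------------------

@dataclass
class EvolutionSpec:
    tree: TreeNode                   # leaf names = genome ids, branch lengths set
    protein_length: int = 200
    rate: float = 1.0                # substitutions per site per unit branch length
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def validate(self) -> None:
        if self.protein_length < 1 or self.rate < 0:
            raise ValueError("invalid protein_length or rate")
        for node in self.tree.traverse(include_self=False):
            if node.length is None or node.length < 0:
                raise ValueError("tree branches need non-negative lengths")


def gen_divergent_proteins(
    spec: EvolutionSpec, n_clogs: int = 20
) -> tuple[dict[tuple[str, str], str], ClogTable]:
    """Evolve gap-free protein families down the tree; one gene per leaf.

    Along a branch of length b each site substitutes with probability
    1 - exp(-b * rate); the replacement is uniform over the alphabet, so two
    leaves at large total distance decay toward a random-match identity of
    1/|alphabet|.  Returns sequences keyed by (genome, gene) and the implied
    single-copy CLOG table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alpha = np.array(list(spec.alphabet))
    leaves = [t.name for t in spec.tree.tips()]
    sequences: dict[tuple[str, str], str] = {}
    clogs: dict[str, list[tuple[str, str]]] = {}
    for c in range(n_clogs):
        cid = f"SC{c + 1:04d}"
        ancestor = rng.integers(0, len(alpha), size=spec.protein_length)

        def evolve(node, seq):
            for child in node.children:
                p = 1.0 - np.exp(-child.length * spec.rate)
                s = seq.copy()
                hit = rng.random(len(s)) < p
                s[hit] = rng.integers(0, len(alpha), size=int(hit.sum()))
                if child.is_tip():
                    gene = f"{cid}_{child.name}"
                    sequences[(child.name, gene)] = "".join(alpha[s])
                else:
                    evolve(child, s)

        evolve(spec.tree, ancestor)
        clogs[cid] = [(g, f"{cid}_{g}") for g in leaves]
    return sequences, ClogTable(clogs, genome_universe=leaves)


def random_tree(n_leaves: int, rng, min_branch: float = 0.05,
                max_branch: float = 1.0) -> TreeNode:
    """Random binary tree with uniform branch lengths (for additivity tests)."""
    labels = [string.ascii_uppercase[i % 26] + (str(i // 26) if i >= 26 else "")
              for i in range(n_leaves)]
    nodes = [TreeNode(name=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_branch, max_branch))
        b.length = float(rng.uniform(min_branch, max_branch))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def random_clog_table(G: int, n_clogs: int, rng,
                      max_genes_per_genome: int = 2) -> ClogTable:
    """Unstructured random ClogTable (for property and oracle tests)."""
    ids = genome_ids(G)
    clogs = {}
    gene_no = 0
    for c in range(n_clogs):
        occ = int(rng.integers(1, G + 1))
        chosen = rng.choice(ids, size=occ, replace=False)
        members = []
        for g in chosen:
            for _ in range(int(rng.integers(1, max_genes_per_genome + 1))):
                gene_no += 1
                members.append((str(g), f"gene{gene_no:06d}"))
        clogs[f"C{c + 1:05d}"] = members
    return ClogTable(clogs, genome_universe=ids)


# ---------------------------------------------------------------------------
# beta-barrel evidence
# ---------------------------------------------------------------------------

@dataclass
class BarrelSimSpec:
    """Evidence generator around a known barrel/non-barrel truth.

    Sensitivity = P(vote | true barrel), specificity = P(no vote | true
    non-barrel), per predictor and for the pHMM search.  Pfam coverage is
    generated so that true barrels keep a long uncovered stretch with
    probability ``pfam_sensitivity`` while non-barrels are fully covered
    with probability ``pfam_specificity``.  Proteins are grouped into
    label-homogeneous CLOGs of size ``clog_size``.
    """

    n_proteins: int = 300
    prevalence: float = 0.3
    G: int = 6
    protein_length: int = 300
    predictor_sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {
            "BOMP": 0.9, "KNN": 0.9, "TMBetaDisc": 0.85, "InHouse+TMHMM": 0.8
        }
    )
    predictor_specificity: Mapping[str, float] = field(
        default_factory=lambda: {
            "BOMP": 0.97, "KNN": 0.95, "TMBetaDisc": 0.95, "InHouse+TMHMM": 0.93
        }
    )
    phmm_sensitivity: float = 0.9
    phmm_specificity: float = 0.99
    pfam_sensitivity: float = 0.95
    pfam_specificity: float = 0.95
    clog_size: int = 3
    families: Sequence[str] = ("Omp85", "LptD", "OprB", "TonB-dep", "OmpA-like")
    seed: int = 0

    def validate(self) -> None:
        rates = (
            [self.prevalence, self.phmm_sensitivity, self.phmm_specificity,
             self.pfam_sensitivity, self.pfam_specificity]
            + list(self.predictor_sensitivity.values())
            + list(self.predictor_specificity.values())
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must be in [0, 1]")


def gen_barrel_evidence(
    spec: BarrelSimSpec,
) -> tuple[list[BarrelEvidence], ClogTable, dict[str, bool]]:
    """Generate evidence rows, the grouping ClogTable, and the truth labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = genome_ids(spec.G)
    evidence: list[BarrelEvidence] = []
    truth: dict[str, bool] = {}
    clogs: dict[str, list[tuple[str, str]]] = {}

    n_barrel = int(round(spec.n_proteins * spec.prevalence))
    labels = [True] * n_barrel + [False] * (spec.n_proteins - n_barrel)

    cid = None
    cid_no = 0
    current_label = None
    for k, is_barrel in enumerate(labels):
        pid = f"p{k + 1:05d}"
        gid = ids[k % len(ids)]
        truth[pid] = is_barrel
        if cid is None or current_label != is_barrel or len(clogs[cid]) >= spec.clog_size:
            cid_no += 1
            cid = f"BC{cid_no:05d}"
            clogs[cid] = []
            current_label = is_barrel
        clogs[cid].append((gid, pid))

        votes = set()
        for pred, sens in spec.predictor_sensitivity.items():
            fpr = 1.0 - spec.predictor_specificity[pred]
            p = sens if is_barrel else fpr
            if rng.random() < p:
                votes.add(pred)
        phmm_hits = []
        p_hit = spec.phmm_sensitivity if is_barrel else 1.0 - spec.phmm_specificity
        if rng.random() < p_hit:
            fam = str(rng.choice(list(spec.families)))
            phmm_hits.append(
                PhmmHit(fam, 1, spec.protein_length,
                        e_value=float(10.0 ** -rng.uniform(10, 50)),
                        bits=float(rng.uniform(50, 500)))
            )
        uncovered_ok = (
            rng.random() < spec.pfam_sensitivity
            if is_barrel
            else rng.random() >= spec.pfam_specificity
        )
        if uncovered_ok:
            intervals = []  # fully uncovered -> long free stretch
        else:
            # tile the protein so that no uncovered run reaches 80 residues
            intervals = []
            pos = 1
            while pos <= spec.protein_length:
                end = min(pos + 60, spec.protein_length)
                intervals.append((pos, end))
                pos = end + 40
        evidence.append(
            BarrelEvidence(
                protein_id=pid,
                genome_id=gid,
                length=spec.protein_length,
                predictor_votes=frozenset(votes),
                phmm_hits=phmm_hits,
                pfam_nonbarrel_intervals=intervals,
                clog_id=cid,
            )
        )
    table = ClogTable(clogs, genome_universe=ids)
    return evidence, table, truth
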
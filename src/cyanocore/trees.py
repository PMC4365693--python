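"""Neighbor-joining trees, AAI and alignment distances, patristic comparison.

Saitou–Nei neighbor joining is implemented directly so that tie-breaking and
negative-branch handling are fully specified: ties in the Q criterion are
broken by the lexicographically smallest pair of subtree labels, and a
negative estimated branch length is clamped to zero with the deficit moved to
its sister branch (the distance between the joined nodes is preserved).
Trees are ``skbio.TreeNode`` objects (newick IO, tip-to-tip distances come
with the container).

The AAI (average amino acid identity) between two strains is the mean global
pairwise-alignment identity over single-copy core CLOGs; 1 - AAI is the tree
distance.  Identity uses all alignment columns (including gaps) in the
denominator by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .clogs import ClogTable, ClogClassification

__all__ = [
    "AlignmentScoring",
    "neighbor_joining",
    "patristic_matrix",
    "patristic_correlation",
    "select_single_copy_core",
    "aai_matrix",
    "msa_p_distance",
]


@dataclass
class AlignmentScoring:
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_denominator: str = "alignment_columns"  # or "shorter_sequence", "ungapped_columns"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree from a distance matrix.

    Iteratively joins the pair minimizing
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); branch lengths by the
    standard two-point formulas.  Deterministic for a given matrix.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = np.array(dm.data, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite entries")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    reps: list[str] = list(labels)  # smallest leaf label under each node

    while len(nodes) > 2:
        r = len(nodes)
        rowsum = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                qij = (r - 2) * d[i, j] - rowsum[i] - rowsum[j]
                key = (qij, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        vj = d[i, j] - vi
        # clamp negatives, moving the deficit to the sister branch
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi = max(vi, 0.0)
        vj = max(vj, 0.0)
        nodes[i].length = vi
        nodes[j].length = vj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        new_d = np.zeros((len(keep) + 1, len(keep) + 1))
        sub = d[np.ix_(keep, keep)]
        new_d[:-1, :-1] = sub
        new_d[-1, :-1] = du[keep]
        new_d[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        d = new_d

    # final join: root at the internal node, full remaining length on the edge
    a, b = nodes
    if a.is_tip() and not b.is_tip():
        a, b = b, a
    b.length = max(d[0, 1], 0.0)
    a.append(b)
    a.length = None
    return a


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances of a tree."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"branch above {node.name or 'internal node'} has no length")
    return tree.tip_tip_distances()


def patristic_correlation(t1: TreeNode, t2: TreeNode) -> float:
    """Pearson correlation of patristic distances over the shared leaf set.

    1 = identical distance structure, -1 = anti-correlated.  Invariant to
    uniform scaling of either tree's branch lengths.
    """
    tips1 = {t.name for t in t1.tips()}
    tips2 = {t.name for t in t2.tips()}
    shared = sorted(tips1 & tips2)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared leaves; need >= 3")
    p1 = patristic_matrix(t1.shear(shared))
    p2 = patristic_matrix(t2.shear(shared))
    iu = np.triu_indices(len(shared), k=1)
    v1 = np.array(p1.filter(shared).data)[iu]
    v2 = np.array(p2.filter(shared).data)[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("patristic distances have zero variance; correlation undefined")
    return float(stats.pearsonr(v1, v2)[0])


# ---------------------------------------------------------------------------
# AAI over single-copy core CLOGs
# ---------------------------------------------------------------------------

def select_single_copy_core(
    table: ClogTable, classification: ClogClassification
) -> set[str]:
    """Core CLOGs where every genome contributes exactly one sequence."""
    out = set()
    G = len(table.genome_universe)
    for cid in classification.of_class("core"):
        members = table.members(cid)
        if len(members) == G and len({g for g, _ in members}) == G:
            out.add(cid)
    return out


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(
        scoring.substitution_matrix
    )
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def global_identity(
    s1: str, s2: str, scoring: AlignmentScoring | None = None
) -> float:
    """Needleman–Wunsch global alignment identity between two sequences."""
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    aln = aligner.align(s1, s2)[0]
    counts = aln.counts()
    if scoring.identity_denominator == "alignment_columns":
        denom = aln.length
    elif scoring.identity_denominator == "shorter_sequence":
        denom = min(len(s1), len(s2))
    elif scoring.identity_denominator == "ungapped_columns":
        denom = counts.identities + counts.mismatches
    else:
        raise ValueError(f"unknown denominator {scoring.identity_denominator!r}")
    return counts.identities / denom


def aai_matrix(
    table: ClogTable,
    single_copy_clogs: set[str],
    sequences: Mapping[tuple[str, str], str],
    scoring: AlignmentScoring | None = None,
) -> DistanceMatrix:
    """1 - AAI distance matrix over all strains.

    ``sequences`` maps (genome_id, gene_id) -> protein sequence; every member
    of every selected CLOG must be present.  Each genome pair is aligned once
    per CLOG and AAI(x, y) is the mean identity over CLOGs.
    """
    if not single_copy_clogs:
        raise ValueError("empty single-copy CLOG selection")
    scoring = scoring or AlignmentScoring()
    genomes = sorted(table.genome_universe)
    per_clog: list[dict[str, str]] = []
    for cid in sorted(single_copy_clogs):
        row = {}
        for g, gene in table.members(cid):
            if (g, gene) not in sequences:
                raise KeyError(f"no sequence for gene {gene!r} of genome {g!r}")
            row[g] = sequences[(g, gene)]
        per_clog.append(row)
    n = len(genomes)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        idents = [
            global_identity(row[genomes[i]], row[genomes[j]], scoring)
            for row in per_clog
        ]
        aai = float(np.mean(idents))
        d[i, j] = d[j, i] = 1.0 - aai
    return DistanceMatrix(d, ids=genomes)


# ---------------------------------------------------------------------------
# p-distances from a multiple sequence alignment
# ---------------------------------------------------------------------------

def msa_p_distance(alignment: Mapping[str, str] | Sequence) -> DistanceMatrix:
    """Pairwise p-distances (mismatches / compared columns) from an MSA.

    Columns with a gap ('-' or '.') in either of the two rows are skipped for
    that pair.  ``alignment`` is a mapping id -> aligned sequence or any
    iterable of records with ``.id`` and ``.seq`` (e.g. Biopython MSA rows).
    """
    if isinstance(alignment, Mapping):
        rows = {k: str(v) for k, v in alignment.items()}
    else:
        rows = {rec.id: str(rec.seq) for rec in alignment}
    ids = list(rows)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError("ragged alignment: rows differ in length")
    n = len(ids)
    gap = {"-", "."}
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = rows[ids[i]], rows[ids[j]]
        compared = mismatch = 0
        for ca, cb in zip(a, b):
            if ca in gap or cb in gap:
                continue
            compared += 1
            if ca != cb:
                mismatch += 1
        if compared == 0:
            raise ValueError(f"no comparable columns for pair ({ids[i]}, {ids[j]})")
        d[i, j] = d[j, i] = mismatch / compared
    return DistanceMatrix(d, ids=ids)
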
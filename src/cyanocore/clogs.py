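"""Ortholog-cluster (CLOG) tables and core/dispensable/unique classification.

A CLOG (CLique of Orthologous Genes) is an ortholog cluster containing one or
more gene sequences from one or more genomes.  The table of all CLOGs over a
genome universe is the central presence/absence structure of the pipeline:
CLOGs covering every genome form the core-genome, CLOGs confined to a single
genome are unique-gene CLOGs (including putative paralog families), and
everything in between is the dispensable-genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClogTable",
    "ClogClassification",
    "classify_clogs",
    "genome_profile",
    "multi_sequence_unique_clogs",
    "clog_similarity",
    "clog_distance_matrix",
]

Member = tuple[str, str]  # (genome_id, gene_id)


class ClogTable:
    """Mapping of CLOG id -> members, over an explicit genome universe.

    Parameters
    ----------
    clogs
        ``clog_id -> [(genome_id, gene_id), ...]``; every CLOG needs at least
        one member and a (genome, gene) pair may belong to one CLOG only.
    genome_universe
        The set of genome ids that "all strains" refers to when calling core
        CLOGs.  Defaults to the set of genomes observed in the members, but an
        explicit universe (from the genome registry) should be preferred: a
        genome with no clustered genes still counts against core calls.
    """

    def __init__(
        self,
        clogs: Mapping[str, Iterable[Member]],
        genome_universe: Iterable[str] | None = None,
    ) -> None:
        self.clogs: dict[str, list[Member]] = {
            cid: [(str(g), str(gene)) for g, gene in members]
            for cid, members in clogs.items()
        }
        observed = {g for members in self.clogs.values() for g, _ in members}
        if genome_universe is None:
            self.genome_universe = set(observed)
        else:
            self.genome_universe = {str(g) for g in genome_universe}
            stray = observed - self.genome_universe
            if stray:
                raise ValueError(
                    f"members reference genomes outside the universe: {sorted(stray)[:5]}"
                )
        seen: set[Member] = set()
        for cid, members in self.clogs.items():
            if not members:
                raise ValueError(f"CLOG {cid!r} has no members")
            for m in members:
                if m in seen:
                    raise ValueError(f"gene {m} assigned to more than one CLOG")
                seen.add(m)
        self._genome_sets: dict[str, frozenset[str]] | None = None

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.clogs)

    def __contains__(self, clog_id: str) -> bool:
        return clog_id in self.clogs

    @property
    def clog_ids(self) -> list[str]:
        return list(self.clogs)

    def members(self, clog_id: str) -> list[Member]:
        return self.clogs[clog_id]

    def genomes_of(self, clog_id: str) -> frozenset[str]:
        """Set of genomes contributing at least one gene to the CLOG."""
        return self.genome_sets()[clog_id]

    def genome_sets(self) -> dict[str, frozenset[str]]:
        if self._genome_sets is None:
            self._genome_sets = {
                cid: frozenset(g for g, _ in members)
                for cid, members in self.clogs.items()
            }
        return self._genome_sets

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence matrix, CLOGs x genomes (sorted ids)."""
        genomes = sorted(self.genome_universe)
        gidx = {g: i for i, g in enumerate(genomes)}
        mat = np.zeros((len(self.clogs), len(genomes)), dtype=bool)
        for row, gs in enumerate(self.genome_sets().values()):
            for g in gs:
                mat[row, gidx[g]] = True
        return pd.DataFrame(mat, index=list(self.clogs), columns=genomes)

    def clogs_of_genome(self, genome_id: str) -> set[str]:
        if genome_id not in self.genome_universe:
            raise KeyError(f"unknown genome {genome_id!r}")
        return {cid for cid, gs in self.genome_sets().items() if genome_id in gs}

    def restrict(self, genomes: Iterable[str]) -> "ClogTable":
        """Sub-table over a genome subset; CLOGs losing all members drop out."""
        keep = {str(g) for g in genomes}
        missing = keep - self.genome_universe
        if missing:
            raise KeyError(f"genomes not in universe: {sorted(missing)}")
        sub = {}
        for cid, members in self.clogs.items():
            mm = [(g, x) for g, x in members if g in keep]
            if mm:
                sub[cid] = mm
        return ClogTable(sub, genome_universe=keep)

    def add_singletons(self, proteome: Mapping[str, Iterable[str]],
                       prefix: str = "SINGLETON") -> "ClogTable":
        """Inject unclustered genes as single-member CLOGs.

        ``proteome`` maps genome_id -> iterable of gene ids (e.g. from a
        proteome FASTA).  Genes already present in some CLOG are skipped.
        """
        assigned = {m for members in self.clogs.values() for m in members}
        clogs = dict(self.clogs)
        universe = set(self.genome_universe)
        i = 0
        for g in sorted(proteome):
            universe.add(str(g))
            for gene in proteome[g]:
                if (str(g), str(gene)) not in assigned:
                    i += 1
                    clogs[f"{prefix}{i}"] = [(str(g), str(gene))]
        return ClogTable(clogs, genome_universe=universe)


@dataclass
class ClogClassification:
    """Per-CLOG core/dispensable/unique class plus summary statistics."""

    classes: dict[str, str]
    counts: dict[str, int]
    occupancy_histogram: dict[int, int] = field(default_factory=dict)

    def of_class(self, cls: str) -> list[str]:
        return [cid for cid, c in self.classes.items() if c == cls]


def classify_clogs(table: ClogTable) -> ClogClassification:
    """Classify every CLOG as core / dispensable / unique.

    core: members from every genome of the universe; unique: members from a
    single genome (any number of sequences — putative paralogs stay unique);
    dispensable: 2..G-1 genomes.  Also tallies the genomes-per-CLOG occupancy
    histogram.
    """
    if not table.genome_universe:
        raise ValueError("genome universe is empty")
    G = len(table.genome_universe)
    classes: dict[str, str] = {}
    occ = Counter()
    for cid, gs in table.genome_sets().items():
        n = len(gs)
        occ[n] += 1
        if n == G:
            classes[cid] = "core"
        elif n == 1:
            classes[cid] = "unique"
        else:
            classes[cid] = "dispensable"
    counts = Counter(classes.values())
    return ClogClassification(
        classes=classes,
        counts={c: counts.get(c, 0) for c in ("core", "dispensable", "unique")},
        occupancy_histogram=dict(sorted(occ.items())),
    )


def genome_profile(
    table: ClogTable, classification: ClogClassification, genome_id: str
) -> dict[str, int]:
    """Gene counts of one genome per CLOG class (genes, not CLOGs)."""
    if genome_id not in table.genome_universe:
        raise KeyError(f"unknown genome {genome_id!r}")
    out = {"core": 0, "dispensable": 0, "unique": 0}
    for cid, members in table.clogs.items():
        cls = classification.classes[cid]
        out[cls] += sum(1 for g, _ in members if g == genome_id)
    return out


def multi_sequence_unique_clogs(
    table: ClogTable, classification: ClogClassification
) -> list[str]:
    """Unique-class CLOGs with >= 2 sequences: putative paralog families."""
    return [
        cid
        for cid in classification.of_class("unique")
        if len(table.members(cid)) >= 2
    ]


def clog_similarity(table: ClogTable, x: str, y: str) -> tuple[float, float]:
    """CLOG-sharing similarity between two strains, and its distance.

    similarity = |CLOGs containing both| / |CLOGs containing either|;
    distance = 1 - similarity.  This is the Jaccard index of the two strains'
    CLOG-presence sets.
    """
    if x == y:
        raise ValueError("self-similarity is only defined via the distance matrix")
    cx = table.clogs_of_genome(x)
    cy = table.clogs_of_genome(y)
    union = len(cx | cy)
    if union == 0:
        raise ValueError(f"similarity undefined: {x!r} and {y!r} share no CLOG universe")
    sim = len(cx & cy) / union
    return sim, 1.0 - sim


def clog_distance_matrix(table: ClogTable):
    """Symmetric 1 - similarity matrix over the universe (zero diagonal)."""
    from skbio import DistanceMatrix

    genomes = sorted(table.genome_universe)
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, dist = clog_similarity(table, genomes[i], genomes[j])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=genomes)
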
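"""COG-category profiling of gene sets and nested clade core-genomes.

Genes carry one-letter COG category annotations.  A gene with two categories
is counted once for each; a gene with more than two collapses to the
synthetic letter X ("multi-process") and is counted under X only.  Along a
chain of nested clades (whole universe down to a single model strain) the
incremental profile counts, at each step, the genes entering that clade's
core-genome that were not already in any larger clade's core — the
increments partition the smallest clade's core gene set exactly.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .clogs import ClogTable

__all__ = [
    "COG_CATEGORIES",
    "SUPER_CATEGORIES",
    "AnnotationMap",
    "CladeChain",
    "aggregate_categories",
    "clade_core_genes",
    "incremental_profile",
    "classify_category_distribution",
]

COG_CATEGORIES = tuple("JKLDVTMNUOCGEFHIPQRS")
MULTI = "X"

SUPER_CATEGORIES = {
    "information": tuple("JKL"),
    "cellular": tuple("DVTMNUO"),
    "metabolism": tuple("CGEFHIP"),
    "poorly_characterized": tuple("QRS"),
}


class AnnotationMap:
    """gene_id -> COG category letters; > 2 categories collapse to X."""

    def __init__(self, annotations: Mapping[str, Iterable[str]]) -> None:
        self._ann: dict[str, tuple[str, ...]] = {}
        valid = set(COG_CATEGORIES)
        for gene, letters in annotations.items():
            letters = tuple(letters)
            bad = set(letters) - valid - {MULTI}
            if bad:
                raise ValueError(f"{gene}: unknown COG letters {sorted(bad)}")
            if len(letters) > 2:
                letters = (MULTI,)
            self._ann[str(gene)] = letters

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._ann

    def __getitem__(self, gene_id: str) -> tuple[str, ...]:
        return self._ann[gene_id]

    def get(self, gene_id: str, default=()) -> tuple[str, ...]:
        return self._ann.get(gene_id, default)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        """``gene_id<TAB>letters`` rows, letters concatenated (e.g. ``KL``)."""
        ann = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            ann[parts[0]] = tuple(parts[1]) if len(parts) > 1 and parts[1] else ()
        return cls(ann)


class CladeChain:
    """Strictly nested genome sets, largest (whole universe) first."""

    def __init__(self, clades: Sequence[Iterable[str]]) -> None:
        self.clades = [frozenset(c) for c in clades]
        if not self.clades:
            raise ValueError("empty chain")
        for big, small in zip(self.clades, self.clades[1:]):
            if not small < big:
                raise ValueError(
                    "chain must be strictly nested, largest clade first"
                )

    def __len__(self) -> int:
        return len(self.clades)

    def __iter__(self):
        return iter(self.clades)

    @classmethod
    def from_file(cls, path: str | Path) -> "CladeChain":
        """One clade per line as comma-separated genome ids, largest first."""
        clades = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            clades.append([g.strip() for g in line.split(",") if g.strip()])
        return cls(clades)


def aggregate_categories(
    genes: Iterable[str], ann: AnnotationMap
) -> dict[str, int]:
    """Category counts for a gene set (dual counting for 2-letter genes).

    Unannotated genes fall under ``unassigned``; super-category totals are
    included under ``super:<name>`` keys (X is excluded from the four
    super-categories).
    """
    counts: Counter = Counter()
    unassigned = 0
    for gene in genes:
        letters = ann.get(gene)
        if not letters:
            unassigned += 1
            continue
        for letter in letters:
            counts[letter] += 1
    out = {c: counts.get(c, 0) for c in COG_CATEGORIES + (MULTI,)}
    out["unassigned"] = unassigned
    for name, members in SUPER_CATEGORIES.items():
        out[f"super:{name}"] = sum(counts.get(c, 0) for c in members)
    return out


def clade_core_genes(
    table: ClogTable, clade: Iterable[str], representative: str
) -> set[str]:
    """Representative's gene ids in the clade's core CLOGs.

    Core here means CLOGs covering every member of the clade; the gene set is
    the projection of those CLOGs onto the representative strain (the strain
    whose functional annotation is used).
    """
    clade = frozenset(clade)
    if representative not in clade:
        raise ValueError(f"representative {representative!r} not in clade")
    out: set[str] = set()
    for cid, gs in table.genome_sets().items():
        if clade <= gs:
            out.update(gene for g, gene in table.members(cid) if g == representative)
    return out


def incremental_profile(
    table: ClogTable,
    chain: CladeChain,
    representative: str,
    ann: AnnotationMap,
) -> dict:
    """Per-step functional increments along a nested clade chain.

    Step i's increment is the representative's genes in chain[i]'s core that
    are in no larger (earlier) clade's core.  Returns per-step gene sets and
    category counts, per-category percentage distribution across steps, and a
    two-bin summary (mass at the whole-universe core vs clade-specific
    cores).
    """
    if representative not in chain.clades[-1]:
        raise ValueError("representative must belong to the smallest clade")
    core_sets = [clade_core_genes(table, c, representative) for c in chain]
    increments: list[set[str]] = []
    seen: set[str] = set()
    for genes in core_sets:
        inc = genes - seen
        increments.append(inc)
        seen |= genes
    step_counts = [aggregate_categories(inc, ann) for inc in increments]

    letters = COG_CATEGORIES + (MULTI,)
    distribution: dict[str, list[float]] = {}
    core_fraction: dict[str, float] = {}
    for letter in letters:
        per_step = [c[letter] for c in step_counts]
        total = sum(per_step)
        if total:
            distribution[letter] = [100.0 * v / total for v in per_step]
            core_fraction[letter] = per_step[0] / total
    return {
        "increments": increments,
        "step_counts": step_counts,
        "distribution_percent": distribution,
        "core_fraction": core_fraction,
    }


def classify_category_distribution(
    core_fraction: Mapping[str, float], threshold: float = 2.0 / 3.0
) -> dict[str, str]:
    """Label each category by where its profile mass sits along the chain.

    ``core-defined`` if more than ``threshold`` of the category's genes enter
    at the whole-universe core step, ``clade-defined`` if more than
    ``threshold`` enters at clade-specific steps, else ``mixed``.
    """
    out = {}
    for letter, frac in core_fraction.items():
        if frac > threshold:
            out[letter] = "core-defined"
        elif (1 - frac) > threshold:
            out[letter] = "clade-defined"
        else:
            out[letter] = "mixed"
    return out
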
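"""Feature-specific CLOG mining and signature-gene confirmation.

A feature-specific CLOG contains sequences exclusively from strains positive
for a phenotype (e.g. heterocyst formation, thermophily).  The exact variant
requires every positive strain to be present; the relaxed variant buckets
candidate CLOGs by support (how many positive strains they cover).  A
candidate gene is promoted to "signature gene" when a homology search against
outgroup genomes (plants, non-cyanobacterial bacteria) returns no qualifying
hit: qualifying means >= 80% coverage of the bait sequence and an e-value of
1e-10 or smaller (both bounds inclusive).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .clogs import ClogTable
from .genome_io import HitRecord

__all__ = [
    "FeatureStrainSet",
    "exact_feature_clogs",
    "relaxed_feature_clogs",
    "marker_profile",
    "specificity_filter",
    "SpecificityReport",
]


@dataclass
class FeatureStrainSet:
    """Strains positive / negative / unassessed for one phenotype feature.

    Strains with unknown status are NOT members: feature-specific mining is
    restricted to confirmed positives.
    """

    feature_name: str
    members: frozenset[str]
    excluded: frozenset[str] = frozenset()
    unknown: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        object.__setattr__(self, "unknown", frozenset(self.unknown))
        if (self.members & self.excluded or self.members & self.unknown
                or self.excluded & self.unknown):
            raise ValueError("member/excluded/unknown sets must be disjoint")

    @classmethod
    def from_file(cls, path: str | Path, feature_name: str = "") -> "FeatureStrainSet":
        """One ``genome_id<TAB>status`` line per strain; status in {+,-,u}."""
        members, excluded, unknown = set(), set(), set()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            gid, status = parts[0].strip(), parts[1].strip() if len(parts) > 1 else "+"
            {"+": members, "-": excluded, "u": unknown}[status].add(gid)
        return cls(feature_name or Path(path).stem, frozenset(members),
                   frozenset(excluded), frozenset(unknown))


def exact_feature_clogs(table: ClogTable, fs: FeatureStrainSet) -> list[str]:
    """CLOGs whose genome set equals the feature's positive strains exactly."""
    if not fs.members:
        raise ValueError("feature strain set has no members")
    return sorted(
        cid for cid, gs in table.genome_sets().items() if gs == fs.members
    )


def relaxed_feature_clogs(
    table: ClogTable, fs: FeatureStrainSet, min_support: int = 1
) -> dict[int, list[str]]:
    """Feature-exclusive CLOGs bucketed by support.

    A CLOG qualifies when its genomes are a subset of the positive strains;
    its support is the number of distinct positive strains it covers.
    Returns ``support -> clog ids`` for every support >= ``min_support``.
    """
    if not 1 <= min_support <= len(fs.members):
        raise ValueError(
            f"min_support {min_support} outside 1..{len(fs.members)}"
        )
    buckets: dict[int, list[str]] = defaultdict(list)
    for cid, gs in table.genome_sets().items():
        if gs and gs <= fs.members and len(gs) >= min_support:
            buckets[len(gs)].append(cid)
    return {k: sorted(v) for k, v in sorted(buckets.items(), reverse=True)}


def relaxed_gene_ids(table: ClogTable, buckets: dict[int, list[str]]) -> set[tuple[str, str]]:
    """Union of (genome, gene) members over all bucketed CLOGs."""
    return {
        m for cids in buckets.values() for cid in cids for m in table.members(cid)
    }


@dataclass
class MarkerProfile:
    per_genome: dict[str, int]          # marker CLOGs containing the genome
    per_class: dict[str, dict[str, int]]
    incomplete_markers: list[str]       # markers missing from >= 1 positive genome


def marker_profile(
    table: ClogTable,
    marker_clogs: list[str],
    classes: dict[str, str],
) -> MarkerProfile:
    """Presence profile of marker CLOGs across strain classes.

    ``classes`` maps genome_id -> 'positive' / 'negative' / 'unknown'.
    Flags markers absent from at least one positive strain (e.g. PatS-like
    markers undetected in some heterocyst formers).
    """
    for cid in marker_clogs:
        if cid not in table:
            raise KeyError(f"marker CLOG {cid!r} not in table")
    per_genome = {
        g: sum(1 for cid in marker_clogs if g in table.genomes_of(cid))
        for g in sorted(table.genome_universe)
    }
    per_class: dict[str, dict[str, int]] = defaultdict(dict)
    for g, count in per_genome.items():
        per_class[classes.get(g, "unknown")][g] = count
    positives = {g for g, c in classes.items() if c == "positive"}
    incomplete = [
        cid for cid in marker_clogs
        if positives - table.genomes_of(cid)
    ]
    return MarkerProfile(per_genome, dict(per_class), incomplete)


@dataclass
class SpecificityReport:
    query_id: str
    qualifying_hits: list[HitRecord] = field(default_factory=list)
    hits_per_taxon: dict[str, int] = field(default_factory=dict)
    organisms_per_taxon: dict[str, int] = field(default_factory=dict)

    @property
    def is_signature(self) -> bool:
        return not self.qualifying_hits


def specificity_filter(
    hits: list[HitRecord],
    min_coverage: float = 0.80,
    max_evalue: float = 1.0e-10,
) -> dict[str, SpecificityReport]:
    """Outgroup specificity filter over a homology hit table.

    A hit qualifies iff coverage >= ``min_coverage`` AND e-value <=
    ``max_evalue`` (both inclusive).  Per query, reports qualifying hits,
    counts per outgroup taxon both by subject sequence and by distinct
    subject organism (subject_id up to the first '|' or whole id), and the
    signature verdict (no qualifying hit anywhere).
    """
    if not 0 <= min_coverage <= 1:
        raise ValueError("min_coverage must be in [0,1]")
    if max_evalue < 0:
        raise ValueError("max_evalue must be >= 0")
    reports: dict[str, SpecificityReport] = {}
    organisms: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for h in hits:
        rep = reports.setdefault(h.query_id, SpecificityReport(h.query_id))
        if h.query_coverage >= min_coverage and h.e_value <= max_evalue:
            rep.qualifying_hits.append(h)
            rep.hits_per_taxon[h.subject_taxon] = (
                rep.hits_per_taxon.get(h.subject_taxon, 0) + 1
            )
            organism = h.subject_id.split("|", 1)[0]
            organisms[h.query_id][h.subject_taxon].add(organism)
    for qid, per_taxon in organisms.items():
        reports[qid].organisms_per_taxon = {t: len(s) for t, s in per_taxon.items()}
    return reports
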
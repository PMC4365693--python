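"""Readers/writers for the external table and sequence formats, plus the
genome registry and the pre-clustering sequence QC rules.

Formats handled here: the OrthoMCL ``groups`` text and a 3-column TSV for
CLOG tables, a TSV genome registry, BLAST tabular (outfmt-6-like with a
configurable column map) homology hits, protein FASTA (via Biopython), and
square-TSV distance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .clogs import ClogTable

logger = logging.getLogger("cyanocore")

__all__ = [
    "GenomeRegistry",
    "ProteinRecord",
    "HitRecord",
    "read_clog_table",
    "write_clog_table",
    "qc_protein",
    "qc_cds_pairing",
    "read_hit_table",
    "read_proteome_fasta",
    "read_distance_matrix",
    "write_distance_matrix",
]


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    genome_id: str
    species: str = ""
    order: str = ""
    genome_size_mb: float | None = None
    orf_count: int | None = None


class GenomeRegistry:
    """The strain universe: ids, labels and order/clade assignments.

    Defines what "all strains" means when calling core CLOGs.
    """

    def __init__(self, genomes: Iterable[GenomeRecord]) -> None:
        self.genomes = list(genomes)
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in registry")
        if any(not g for g in ids):
            raise ValueError("empty genome_id in registry")
        self._by_id = {g.genome_id: g for g in self.genomes}

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def __len__(self) -> int:
        return len(self.genomes)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._by_id

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self._by_id[genome_id]

    def order_of(self, genome_id: str) -> str:
        return self._by_id[genome_id].order

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeRegistry":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"genome_id"}
        if not required <= set(df.columns):
            raise ValueError(f"registry TSV needs columns {sorted(required)}")
        recs = []
        for _, row in df.iterrows():
            recs.append(
                GenomeRecord(
                    genome_id=row["genome_id"],
                    species=row.get("species", ""),
                    order=row.get("order", ""),
                    genome_size_mb=float(row["genome_size_mb"])
                    if row.get("genome_size_mb", "") != ""
                    else None,
                    orf_count=int(float(row["orf_count"]))
                    if row.get("orf_count", "") != ""
                    else None,
                )
            )
        return cls(recs)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "genome_id": g.genome_id,
                "species": g.species,
                "order": g.order,
                "genome_size_mb": g.genome_size_mb,
                "orf_count": g.orf_count,
            }
            for g in self.genomes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence records and QC
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    gene_id: str
    genome_id: str
    sequence: str  # may contain '*' for (internal) stop codons


def qc_protein(rec: ProteinRecord) -> str:
    """Pre-clustering QC verdict: ``pass``, ``fail_short`` or ``fail_stops``.

    Sequences shorter than 10 residues, or with a stop-codon ('*') frequency
    above 20%, are excluded from ortholog clustering.  Every character counts
    toward length; ambiguity codes are ordinary residues.
    """
    if not rec.sequence:
        raise ValueError(f"{rec.gene_id}: empty sequence")
    n = len(rec.sequence)
    if n < 10:
        return "fail_short"
    if rec.sequence.count("*") / n > 0.20:
        return "fail_stops"
    return "pass"


def qc_cds_pairing(cds_length: int, protein_length: int) -> bool:
    """Check the 3:1 CDS:protein length relation.

    Accepts both 3L (stop codon not in the CDS) and 3(L+1) (stop codon
    included) — both are valid encodings; anything else indicates a
    mis-annotated pair.
    """
    if cds_length <= 0 or protein_length <= 0:
        raise ValueError("lengths must be positive")
    return cds_length in (3 * protein_length, 3 * (protein_length + 1))


def read_proteome_fasta(path: str | Path, genome_id: str) -> list[ProteinRecord]:
    return [
        ProteinRecord(gene_id=rec.id, genome_id=genome_id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# CLOG tables
# ---------------------------------------------------------------------------

def read_clog_table(
    path: str | Path,
    format: str = "orthomcl_groups",
    genome_universe: Iterable[str] | None = None,
) -> ClogTable:
    """Read a CLOG table from OrthoMCL ``groups`` text or 3-column TSV.

    orthomcl_groups: ``clog_id: genome|gene genome|gene ...`` per line; the
    member token splits on the FIRST ``|`` so gene ids may contain ``|``.
    tsv: one ``clog_id<TAB>genome_id<TAB>gene_id`` row per member (header
    optional, detected by a ``clog_id`` first field).
    """
    path = Path(path)
    clogs: dict[str, list[tuple[str, str]]] = {}
    if format == "orthomcl_groups":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: missing 'clog_id:' prefix")
            cid, rest = line.split(":", 1)
            cid = cid.strip()
            members = []
            for tok in rest.split():
                if "|" not in tok:
                    raise ValueError(
                        f"{path}:{lineno}: member token {tok!r} lacks 'genome|gene'"
                    )
                g, gene = tok.split("|", 1)
                members.append((g, gene))
            clogs.setdefault(cid, []).extend(members)
    elif format == "tsv":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "clog_id":
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            cid, g, gene = parts[0], parts[1], parts[2]
            clogs.setdefault(cid, []).append((g, gene))
    else:
        raise ValueError(f"unknown CLOG table format {format!r}")

    seen = set()
    for cid, members in clogs.items():
        for m in members:
            if (cid, m) in seen:
                raise ValueError(f"duplicate member {m} in CLOG {cid}")
            seen.add((cid, m))
    return ClogTable(clogs, genome_universe=genome_universe)


def write_clog_table(table: ClogTable, path: str | Path,
                     format: str = "orthomcl_groups") -> None:
    """Write a CLOG table; members canonically sorted for reproducibility."""
    path = Path(path)
    lines = []
    for cid in sorted(table.clogs):
        members = sorted(table.members(cid))
        if format == "orthomcl_groups":
            toks = " ".join(f"{g}|{gene}" for g, gene in members)
            lines.append(f"{cid}: {toks}")
        elif format == "tsv":
            lines.extend(f"{cid}\t{g}\t{gene}" for g, gene in members)
        else:
            raise ValueError(f"unknown CLOG table format {format!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------

@dataclass
class HitRecord:
    query_id: str
    subject_id: str
    subject_taxon: str
    query_coverage: float  # fraction of the query (bait) covered
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(f"coverage {self.query_coverage} outside [0,1]")
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")


DEFAULT_HIT_COLUMNS = {"query": 0, "subject": 1, "taxon": 2, "coverage": 3, "evalue": 4}


def read_hit_table(
    path: str | Path,
    columns: Mapping[str, int] = DEFAULT_HIT_COLUMNS,
    coverage_unit: str = "percent",
) -> list[HitRecord]:
    """Read a BLAST-tabular-like hit file into HitRecords.

    ``columns`` maps the roles query/subject/taxon/coverage/evalue to 0-based
    column indices.  ``coverage_unit`` is ``percent`` (qcovs-style, normalized
    to a fraction) or ``fraction``.
    """
    hits: list[HitRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            cov = float(parts[columns["coverage"]])
            ev = float(parts[columns["evalue"]])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if coverage_unit == "percent":
            if not 0.0 <= cov <= 100.0:
                raise ValueError(f"{path}:{lineno}: coverage {cov} outside [0,100]")
            cov /= 100.0
        hits.append(
            HitRecord(
                query_id=parts[columns["query"]],
                subject_id=parts[columns["subject"]],
                subject_taxon=parts[columns["taxon"]],
                query_coverage=cov,
                e_value=ev,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# distance matrices as square TSV
# ---------------------------------------------------------------------------

def write_distance_matrix(dm, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path):
    from skbio import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(np.asarray(df.values, dtype=float),
                          ids=[str(i) for i in df.index])
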
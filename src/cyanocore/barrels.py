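"""Consensus categorization of β-barrel outer-membrane proteins.

Four criteria are combined per protein:

* **TMBp** (major): called β-barrel by more than one sequence-based predictor
  (BOMP / KNN / TMBetaDisc / in-house+TMHMM roster) — at least two votes.
* **pHMM** (major): at least one β-barrel domain family hit by profile HMMs.
* **Pfam** (minor): *potential* if some stretch longer than 79 residues is
  not covered by any non-β-barrel Pfam domain.
* **CLOG** (minor): *detected* if the protein passes both majors and more
  than 50% of all sequences of its ortholog cluster pass both majors.

Categories: (a) both majors + both minors; (b) both majors + exactly one
minor; (c) both majors only, retained after structural (Phyre2-style) manual
confirmation; (d) everything else.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .clogs import ClogTable
from .genome_io import GenomeRegistry

__all__ = [
    "BarrelEvidence",
    "BarrelCall",
    "PhmmHit",
    "DEFAULT_PREDICTOR_ROSTER",
    "tmbp_consensus",
    "phmm_probable",
    "best_family",
    "pfam_potential",
    "clog_detected",
    "categorize",
    "categorize_all",
    "family_summary",
    "read_evidence_table",
]

DEFAULT_PREDICTOR_ROSTER = frozenset(
    {"BOMP", "KNN", "TMBetaDisc", "InHouse+TMHMM"}
)


@dataclass
class PhmmHit:
    family: str
    start: int
    end: int
    e_value: float = 1.0
    bits: float = 0.0


@dataclass
class BarrelEvidence:
    protein_id: str
    genome_id: str
    length: int
    predictor_votes: frozenset[str] = frozenset()
    phmm_hits: list[PhmmHit] = field(default_factory=list)
    pfam_nonbarrel_intervals: list[tuple[int, int]] = field(default_factory=list)
    clog_id: str | None = None
    structural_override: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictor_votes", frozenset(self.predictor_votes))
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: non-positive length")
        for s, e in self.pfam_nonbarrel_intervals:
            if not (1 <= s <= e <= self.length):
                raise ValueError(
                    f"{self.protein_id}: Pfam interval [{s},{e}] outside [1,{self.length}]"
                )


@dataclass
class BarrelCall:
    protein_id: str
    tmbp_probable: bool
    phmm_probable: bool
    pfam_potential: bool
    clog_detected: bool
    category: str  # 'a' | 'b' | 'c' | 'd'
    family: str | None = None


def tmbp_consensus(
    ev: BarrelEvidence, roster: frozenset[str] = DEFAULT_PREDICTOR_ROSTER
) -> bool:
    """Probable by sequence predictors: more than one predictor voted."""
    stray = ev.predictor_votes - roster
    if stray:
        raise ValueError(
            f"{ev.protein_id}: votes from unknown predictors {sorted(stray)}"
        )
    return len(ev.predictor_votes) >= 2


def phmm_probable(ev: BarrelEvidence) -> bool:
    """Probable by profile HMMs: at least one β-barrel family hit."""
    return bool(ev.phmm_hits)


def best_family(ev: BarrelEvidence) -> str | None:
    """Family of the best pHMM hit (lowest e-value, ties by bits then name)."""
    if not ev.phmm_hits:
        return None
    return min(ev.phmm_hits, key=lambda h: (h.e_value, -h.bits, h.family)).family


def pfam_potential(ev: BarrelEvidence) -> bool:
    """Potential β-barrel: an uncovered stretch longer than 79 residues.

    Non-β-barrel Pfam intervals are merged; the verdict is true iff the
    longest run of residues outside every interval is >= 80.
    """
    merged: list[list[int]] = []
    for s, e in sorted(ev.pfam_nonbarrel_intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    pos = 1
    longest = 0
    for s, e in merged:
        longest = max(longest, s - pos)
        pos = e + 1
    longest = max(longest, ev.length - pos + 1)
    return longest >= 80


def clog_detected(
    table: ClogTable, major_pass: dict[str, bool],
    evidence: Iterable[BarrelEvidence],
) -> dict[str, bool]:
    """CLOG-vote minor criterion, per protein.

    ``major_pass`` maps protein_id -> (tmbp AND phmm).  A CLOG passes when
    the fraction of its members passing both majors is strictly greater than
    50%; members without an evidence row count as non-passing.  A protein's
    flag is true iff its CLOG passes and the protein itself passes both
    majors; proteins without a CLOG get false.
    """
    ev_by_id = {e.protein_id: e for e in evidence}
    clog_frac: dict[str, float] = {}
    for cid, members in table.clogs.items():
        passing = sum(1 for _, gene in members if major_pass.get(gene, False))
        clog_frac[cid] = passing / len(members)
    out: dict[str, bool] = {}
    for pid, e in ev_by_id.items():
        if e.clog_id is None or e.clog_id not in clog_frac:
            out[pid] = False
        else:
            out[pid] = clog_frac[e.clog_id] > 0.5 and major_pass.get(pid, False)
    return out


def categorize(
    ev: BarrelEvidence,
    tmbp: bool,
    phmm: bool,
    pfam: bool,
    clog: bool,
) -> BarrelCall:
    """Assign the consensus category from the four criterion flags.

    Both majors are required for a/b/c; the number of satisfied minors picks
    a (2) or b (1); with no minor satisfied, only a structural override keeps
    the protein as c, otherwise it falls to d.
    """
    if not (tmbp and phmm):
        cat = "d"
    else:
        minors = int(pfam) + int(clog)
        if minors == 2:
            cat = "a"
        elif minors == 1:
            cat = "b"
        else:
            cat = "c" if ev.structural_override else "d"
    return BarrelCall(
        protein_id=ev.protein_id,
        tmbp_probable=tmbp,
        phmm_probable=phmm,
        pfam_potential=pfam,
        clog_detected=clog,
        category=cat,
        family=best_family(ev),
    )


def categorize_all(
    evidence: list[BarrelEvidence],
    table: ClogTable | None = None,
    roster: frozenset[str] = DEFAULT_PREDICTOR_ROSTER,
) -> list[BarrelCall]:
    """Run the full four-criterion consensus over an evidence list."""
    majors = {
        e.protein_id: tmbp_consensus(e, roster) and phmm_probable(e)
        for e in evidence
    }
    if table is not None:
        clog_flags = clog_detected(table, majors, evidence)
    else:
        clog_flags = {e.protein_id: False for e in evidence}
    return [
        categorize(
            e,
            tmbp_consensus(e, roster),
            phmm_probable(e),
            pfam_potential(e),
            clog_flags[e.protein_id],
        )
        for e in evidence
    ]


def family_summary(
    calls: list[BarrelCall],
    evidence: list[BarrelEvidence],
    registry: GenomeRegistry,
) -> dict[str, dict[str, int]]:
    """Per pHMM family: distinct strains, distinct orders, sequence count.

    Only category a/b/c calls (the accepted β-barrel set) are tallied.
    """
    ev_by_id = {e.protein_id: e for e in evidence}
    fam: dict[str, dict[str, set | int]] = defaultdict(
        lambda: {"strains": set(), "orders": set(), "sequences": 0}
    )
    for call in calls:
        if call.category == "d" or call.family is None:
            continue
        e = ev_by_id[call.protein_id]
        fam[call.family]["strains"].add(e.genome_id)
        if e.genome_id in registry:
            fam[call.family]["orders"].add(registry.order_of(e.genome_id))
        fam[call.family]["sequences"] += 1
    return {
        f: {
            "strains": len(v["strains"]),
            "orders": len(v["orders"]),
            "sequences": v["sequences"],
        }
        for f, v in sorted(fam.items())
    }


# ---------------------------------------------------------------------------
# evidence TSV
# ---------------------------------------------------------------------------
# Columns: protein_id, genome_id, length, votes (';'-joined), phmm hits
# ("family:start-end:evalue:bits" ';'-joined), pfam intervals ("start-end"
# ';'-joined), clog_id ('-' for none), override (0/1).

def read_evidence_table(path: str | Path) -> list[BarrelEvidence]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "protein_id":
            continue
        if len(parts) < 8:
            raise ValueError(f"{path}:{lineno}: expected 8 columns")
        pid, gid, length, votes, phmm, pfam, clog, override = parts[:8]
        hits = []
        if phmm:
            for tok in phmm.split(";"):
                fam, span, ev, bits = tok.split(":")
                s, e = span.split("-")
                hits.append(PhmmHit(fam, int(s), int(e), float(ev), float(bits)))
        intervals = []
        if pfam:
            for tok in pfam.split(";"):
                s, e = tok.split("-")
                intervals.append((int(s), int(e)))
        out.append(
            BarrelEvidence(
                protein_id=pid,
                genome_id=gid,
                length=int(length),
                predictor_votes=frozenset(votes.split(";")) if votes else frozenset(),
                phmm_hits=hits,
                pfam_nonbarrel_intervals=intervals,
                clog_id=None if clog in ("-", "") else clog,
                structural_override=override == "1",
            )
        )
    return out


def write_evidence_table(evidence: list[BarrelEvidence], path: str | Path) -> None:
    lines = ["protein_id\tgenome_id\tlength\tvotes\tphmm\tpfam\tclog_id\toverride"]
    for e in evidence:
        lines.append(
            "\t".join(
                [
                    e.protein_id,
                    e.genome_id,
                    str(e.length),
                    ";".join(sorted(e.predictor_votes)),
                    ";".join(
                        f"{h.family}:{h.start}-{h.end}:{h.e_value}:{h.bits}"
                        for h in e.phmm_hits
                    ),
                    ";".join(f"{s}-{e_}" for s, e_ in e.pfam_nonbarrel_intervals),
                    e.clog_id or "-",
                    "1" if e.structural_override else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
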
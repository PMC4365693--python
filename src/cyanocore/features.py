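"""Phenotype feature fingerprints and the Tanimoto-like similarity index.

Each strain is described by a fixed list of features (habitat, morphology,
nitrogen fixation, ...), each feature by a bit string over its subcategories
(present = 1 / absent = 0) or by the sentinel ``unknown`` when no information
exists.  The Tanimoto-like index between two strains accumulates, over the
features, popcount of the bitwise AND into the numerator and of the bitwise
OR into the denominator; a feature unknown in both strains is skipped, and a
feature known in exactly one strain adds 0.5 to the denominator only.  With
no unknowns and single-bit features the index reduces to the classical
Tanimoto/Jaccard coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FeatureTable",
    "SimilarityResult",
    "InferenceRule",
    "tanimoto_similarity",
    "feature_distance_matrix",
    "known_info_counts",
    "apply_inference_rules",
]

UNKNOWN = None  # sentinel for "no information available" (file token: "u")


class FeatureTable:
    """genome x feature table of subcategory bit strings, with unknowns.

    ``features`` is an ordered list of ``(feature_name, [subcategory, ...])``;
    ``values[genome][feature]`` is a frozenset of present subcategory names
    (possibly empty: assessed, all absent) or ``None`` for unknown.
    """

    def __init__(
        self,
        features: Iterable[tuple[str, Iterable[str]]],
        values: Mapping[str, Mapping[str, frozenset | None]],
    ) -> None:
        self.features: list[tuple[str, tuple[str, ...]]] = [
            (name, tuple(subs)) for name, subs in features
        ]
        self._subcats = {name: set(subs) for name, subs in self.features}
        self.values: dict[str, dict[str, frozenset | None]] = {}
        for g, fv in values.items():
            row: dict[str, frozenset | None] = {}
            for name, _ in self.features:
                v = fv.get(name, UNKNOWN)
                if v is not UNKNOWN:
                    v = frozenset(v)
                    bad = v - self._subcats[name]
                    if bad:
                        raise ValueError(
                            f"{g}/{name}: unknown subcategories {sorted(bad)}"
                        )
                row[name] = v
            self.values[str(g)] = row

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values)

    def bits(self, genome_id: str, feature: str) -> np.ndarray | None:
        """Bit vector over the feature's ordered subcategories, or None."""
        v = self.values[genome_id][feature]
        if v is UNKNOWN:
            return None
        subs = dict(self.features)[feature]
        return np.array([s in v for s in subs], dtype=bool)

    # -- TSV round trip ----------------------------------------------------
    # One row per genome, one column per feature.  Cell values: subcategory
    # names joined by ';', empty cell = known all-zero, 'u' = unknown.  An
    # optional '#subcategories' line after the header pins each feature's
    # subcategory order; otherwise subcategories are inferred from the data.

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
        header = lines[0].split("\t")
        if header[0] != "genome_id":
            raise ValueError("feature TSV must start with a 'genome_id' column")
        feat_names = header[1:]
        body = lines[1:]
        declared: dict[str, tuple[str, ...]] | None = None
        if body and body[0].startswith("#subcategories"):
            toks = body[0].split("\t")[1:]
            if len(toks) != len(feat_names):
                raise ValueError("#subcategories line does not match the header")
            declared = {
                f: tuple(t.split(";")) if t else ()
                for f, t in zip(feat_names, toks)
            }
            body = body[1:]
        raw: dict[str, dict[str, frozenset | None]] = {}
        observed: dict[str, set[str]] = {f: set() for f in feat_names}
        for line in body:
            parts = line.split("\t")
            g = parts[0]
            row: dict[str, frozenset | None] = {}
            for f, cell in zip(feat_names, parts[1:]):
                cell = cell.strip()
                if cell == "u":
                    row[f] = UNKNOWN
                elif cell == "":
                    row[f] = frozenset()
                else:
                    v = frozenset(cell.split(";"))
                    observed[f] |= v
                    row[f] = v
            raw[g] = row
        features = [
            (f, declared[f] if declared else tuple(sorted(observed[f])))
            for f in feat_names
        ]
        return cls(features, raw)

    def to_tsv(self, path: str | Path) -> None:
        names = [f for f, _ in self.features]
        lines = ["\t".join(["genome_id"] + names)]
        lines.append(
            "\t".join(["#subcategories"] + [";".join(s) for _, s in self.features])
        )
        for g in self.genome_ids:
            cells = []
            for f, subs in self.features:
                v = self.values[g][f]
                if v is UNKNOWN:
                    cells.append("u")
                else:
                    cells.append(";".join(s for s in subs if s in v))
            lines.append("\t".join([g] + cells))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SimilarityResult:
    numerator: float
    denominator: float
    features_used: int
    features_skipped: int

    @property
    def similarity(self) -> float:
        if self.denominator == 0:
            raise ZeroDivisionError("similarity undefined (denominator 0)")
        return self.numerator / self.denominator

    @property
    def distance(self) -> float:
        return 1.0 - self.similarity


def tanimoto_similarity(ft: FeatureTable, x: str, y: str) -> SimilarityResult:
    """Tanimoto-like index between two strains with unknown handling.

    Per feature: unknown in both -> skipped; unknown in exactly one ->
    denominator += 0.5; known in both -> numerator += |AND|, denominator
    += |OR|.  Raises if every feature ends up contributing nothing.
    """
    if x not in ft.values or y not in ft.values:
        missing = [g for g in (x, y) if g not in ft.values]
        raise KeyError(f"genomes not in feature table: {missing}")
    num = 0.0
    den = 0.0
    used = skipped = 0
    for fname, _ in ft.features:
        vx = ft.values[x][fname]
        vy = ft.values[y][fname]
        if vx is UNKNOWN and vy is UNKNOWN:
            skipped += 1
            continue
        used += 1
        if vx is UNKNOWN or vy is UNKNOWN:
            den += 0.5
        else:
            num += len(vx & vy)
            den += len(vx | vy)
    res = SimilarityResult(num, den, used, skipped)
    if den == 0:
        raise ValueError(
            f"similarity undefined for pair ({x!r}, {y!r}): denominator 0"
        )
    return res


def feature_distance_matrix(
    ft: FeatureTable,
    allow_missing: bool = False,
    missing_distance: float = 1.0,
):
    """Symmetric 1 - similarity matrix over all strains of the table.

    Pairs with an undefined index (denominator 0) abort the construction
    unless ``allow_missing`` substitutes ``missing_distance`` for them.
    """
    from skbio import DistanceMatrix

    ids = ft.genome_ids
    if len(ids) < 2:
        raise ValueError("need >= 2 genomes")
    n = len(ids)
    d = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = tanimoto_similarity(ft, ids[i], ids[j]).distance
            except ValueError:
                if allow_missing:
                    d[i, j] = d[j, i] = missing_distance
                else:
                    undefined.append((ids[i], ids[j]))
    if undefined:
        raise ValueError(f"undefined similarity for pairs: {undefined}")
    return DistanceMatrix(d, ids=ids)


def known_info_counts(ft: FeatureTable) -> dict[str, int]:
    """Per feature, the number of strains with a known (non-unknown) value."""
    return {
        fname: sum(1 for g in ft.genome_ids if ft.values[g][fname] is not UNKNOWN)
        for fname, _ in ft.features
    }


# ---------------------------------------------------------------------------
# logical inference on unknowns
# ---------------------------------------------------------------------------

@dataclass
class InferenceRule:
    """If a strain has ``when_subcategory`` set in ``when_feature`` and its
    ``set_feature`` is unknown, fill it with ``set_value`` (possibly the empty
    set, i.e. "assessed, all absent")."""

    when_feature: str
    when_subcategory: str
    set_feature: str
    set_value: frozenset = field(default_factory=frozenset)

    @staticmethod
    def from_tsv(path: str | Path) -> list["InferenceRule"]:
        rules = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"rule line needs 4 fields: {line!r}")
            wf, ws, sf, sv = parts[:4]
            rules.append(
                InferenceRule(wf, ws, sf,
                              frozenset(sv.split(";")) if sv else frozenset())
            )
        return rules


def apply_inference_rules(
    ft: FeatureTable, rules: Iterable[InferenceRule], logger=None
) -> FeatureTable:
    """Apply logical-assumption rules, returning a new table.

    Only unknown cells are ever filled; every application is logged.
    """
    values = {g: dict(row) for g, row in ft.values.items()}
    for rule in rules:
        for g, row in values.items():
            cond = row.get(rule.when_feature)
            if cond is UNKNOWN or cond is None:
                continue
            if rule.when_subcategory in cond and row.get(rule.set_feature) is UNKNOWN:
                row[rule.set_feature] = frozenset(rule.set_value)
                if logger is not None:
                    logger.info(
                        "inference: %s/%s <- %r (because %s has %s)",
                        g, rule.set_feature, sorted(rule.set_value),
                        rule.when_feature, rule.when_subcategory,
                    )
    return FeatureTable(ft.features, values)
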
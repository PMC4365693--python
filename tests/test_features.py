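"""Tanimoto-like feature index: stated rules, oracle equivalence, limits."""

import numpy as np
import pytest

from cyanocore.features import (
    FeatureTable,
    InferenceRule,
    apply_inference_rules,
    feature_distance_matrix,
    known_info_counts,
    tanimoto_similarity,
)
from cyanocore.synthetic import gen_feature_table, genome_ids


def brute_force_tanimoto(ft, x, y):
    """Independent re-statement of the index rules on raw bit vectors."""
    num = den = 0.0
    for fname, subs in ft.features:
        bx = ft.bits(x, fname)
        by = ft.bits(y, fname)
        if bx is None and by is None:
            continue
        if bx is None or by is None:
            den += 0.5
            continue
        num += int(np.sum(bx & by))
        den += int(np.sum(bx | by))
    return num, den


def random_feature_table(rng, G=8, F=6, unknown_rate=0.25):
    feats = [(f"f{i}", tuple(f"s{j}" for j in range(int(rng.integers(1, 5)))))
             for i in range(F)]
    values = {}
    for g in genome_ids(G):
        row = {}
        for name, subs in feats:
            if rng.random() < unknown_rate:
                row[name] = None
            else:
                row[name] = frozenset(s for s in subs if rng.random() < 0.5)
        values[g] = row
    return FeatureTable(feats, values)


class TestStatedRules:
    def test_known_in_both(self):
        ft = FeatureTable([("f1", ("a", "b"))],
                          {"x": {"f1": {"a"}}, "y": {"f1": {"a", "b"}}})
        r = tanimoto_similarity(ft, "x", "y")
        assert (r.numerator, r.denominator) == (1, 2)
        assert r.similarity == pytest.approx(0.5)

    def test_half_known_denominator_increment(self):
        ft = FeatureTable(
            [("f1", ("a", "b")), ("f2", ("c",))],
            {"x": {"f1": {"a"}, "f2": None}, "y": {"f1": {"a", "b"}, "f2": {"c"}}},
        )
        r = tanimoto_similarity(ft, "x", "y")
        assert r.numerator == pytest.approx(1)
        assert r.denominator == pytest.approx(2.5)
        assert r.similarity == pytest.approx(0.4)

    def test_identity_pair_is_one(self):
        ft = FeatureTable([("f1", ("a", "b")), ("f2", ("c",))],
                          {"x": {"f1": {"a"}, "f2": {"c"}}})
        assert tanimoto_similarity(ft, "x", "x").similarity == 1.0

    def test_unknown_in_both_skipped_entirely(self):
        with_unknown = FeatureTable(
            [("f1", ("a",)), ("f2", ("b",))],
            {"x": {"f1": {"a"}, "f2": None}, "y": {"f1": {"a"}, "f2": None}},
        )
        without = FeatureTable([("f1", ("a",))],
                               {"x": {"f1": {"a"}}, "y": {"f1": {"a"}}})
        ra = tanimoto_similarity(with_unknown, "x", "y")
        rb = tanimoto_similarity(without, "x", "y")
        assert (ra.numerator, ra.denominator) == (rb.numerator, rb.denominator)
        assert ra.features_skipped == 1

    def test_all_zero_known_feature_contributes_nothing(self):
        ft = FeatureTable(
            [("f1", ("a",)), ("f2", ("b",))],
            {"x": {"f1": {"a"}, "f2": frozenset()},
             "y": {"f1": {"a"}, "f2": frozenset()}},
        )
        r = tanimoto_similarity(ft, "x", "y")
        assert (r.numerator, r.denominator) == (1, 1)

    def test_undefined_pair_raises(self):
        ft = FeatureTable([("f1", ("a",))], {"x": {"f1": None}, "y": {"f1": None}})
        with pytest.raises(ValueError, match="undefined"):
            tanimoto_similarity(ft, "x", "y")

    def test_feature_known_in_one_decreases_similarity(self):
        base = FeatureTable([("f1", ("a",))],
                            {"x": {"f1": {"a"}}, "y": {"f1": {"a"}}})
        extended = FeatureTable(
            [("f1", ("a",)), ("f2", ("b",))],
            {"x": {"f1": {"a"}, "f2": {"b"}}, "y": {"f1": {"a"}, "f2": None}},
        )
        assert tanimoto_similarity(extended, "x", "y").similarity < \
            tanimoto_similarity(base, "x", "y").similarity


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_pairs(self, rng):
        checked = 0
        while checked < 300:
            ft = random_feature_table(rng)
            ids = ft.genome_ids
            x, y = rng.choice(ids, size=2, replace=False)
            num, den = brute_force_tanimoto(ft, x, y)
            if den == 0:
                with pytest.raises(ValueError):
                    tanimoto_similarity(ft, x, y)
            else:
                r = tanimoto_similarity(ft, x, y)
                assert r.numerator == pytest.approx(num)
                assert r.denominator == pytest.approx(den)
                assert r.similarity == pytest.approx(
                    tanimoto_similarity(ft, y, x).similarity
                )
            checked += 1

    def test_reduces_to_jaccard_without_unknowns(self, rng):
        # single-subcategory binary features, no unknowns -> classical
        # Tanimoto/Jaccard on the concatenated bit vectors
        from scipy.spatial.distance import jaccard

        for _ in range(20):
            F = 10
            feats = [(f"f{i}", ("s",)) for i in range(F)]
            a = rng.integers(0, 2, size=F).astype(bool)
            b = rng.integers(0, 2, size=F).astype(bool)
            if not (a | b).any():
                continue
            values = {
                "x": {f"f{i}": ({"s"} if a[i] else frozenset()) for i in range(F)},
                "y": {f"f{i}": ({"s"} if b[i] else frozenset()) for i in range(F)},
            }
            ft = FeatureTable(feats, values)
            expected = 1.0 - jaccard(a, b)
            assert tanimoto_similarity(ft, "x", "y").similarity == \
                pytest.approx(expected)


class TestDistanceMatrix:
    def test_identical_fingerprints_zero_distance(self):
        ft = FeatureTable([("f1", ("a",))],
                          {"x": {"f1": {"a"}}, "y": {"f1": {"a"}}})
        dm = feature_distance_matrix(ft)
        assert dm["x", "y"] == 0.0

    def test_elementwise_equals_pair_function(self, rng):
        for _ in range(10):
            ft = random_feature_table(rng, unknown_rate=0.1)
            try:
                dm = feature_distance_matrix(ft)
            except ValueError:
                continue
            ids = ft.genome_ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    assert dm[ids[i], ids[j]] == pytest.approx(
                        tanimoto_similarity(ft, ids[i], ids[j]).distance
                    )

    def test_clade_structure_separates_distances(self):
        ids = genome_ids(10)
        clades = {"A": ids[:5], "B": ids[5:]}
        feats = [(f"f{i}", ("x", "y", "z")) for i in range(13)]
        fingerprints = {
            "A": {f"f{i}": frozenset({"x"}) for i in range(13)},
            "B": {f"f{i}": frozenset({"y", "z"}) for i in range(13)},
        }
        ft, truth = gen_feature_table(clades, feats, unknown_rate=0.0, seed=0,
                                      fingerprints=fingerprints)
        dm = feature_distance_matrix(ft)
        within, between = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                d = dm[ids[i], ids[j]]
                (within if truth["clades"][ids[i]] == truth["clades"][ids[j]]
                 else between).append(d)
        assert np.mean(within) < np.mean(between)
        assert max(within) == 0.0 and min(between) == 1.0

    def test_allow_missing_substitutes_distance(self):
        ft = FeatureTable([("f1", ("a",))],
                          {"x": {"f1": None}, "y": {"f1": None},
                           "z": {"f1": {"a"}}})
        with pytest.raises(ValueError):
            feature_distance_matrix(ft)
        dm = feature_distance_matrix(ft, allow_missing=True, missing_distance=0.9)
        assert dm["x", "y"] == pytest.approx(0.9)


class TestKnownInfoCounts:
    def test_all_unknown_feature(self):
        ft = FeatureTable([("f1", ("a",))], {"x": {"f1": None}, "y": {"f1": None}})
        assert known_info_counts(ft) == {"f1": 0}

    def test_counts_match_generator_mask(self):
        ids = genome_ids(20)
        feats = [(f"f{i}", ("s1", "s2")) for i in range(13)]
        ft, truth = gen_feature_table({"all": ids}, feats, unknown_rate=0.3, seed=4)
        counts = known_info_counts(ft)
        for fname, _ in feats:
            expected = sum(1 for g in ids if not truth["mask"][(g, fname)])
            assert counts[fname] == expected


class TestTsvAndInference:
    def test_tsv_round_trip(self, rng, tmp_path):
        ft = random_feature_table(rng)
        path = tmp_path / "features.tsv"
        ft.to_tsv(path)
        back = FeatureTable.from_tsv(path)
        assert back.features == ft.features
        assert back.values == ft.values

    def test_inference_fills_only_unknowns(self):
        ft = FeatureTable(
            [("cell_type", ("unicellular", "filamentous")),
             ("heterocysts", ("present",))],
            {
                "x": {"cell_type": {"unicellular"}, "heterocysts": None},
                "y": {"cell_type": {"filamentous"}, "heterocysts": None},
                "z": {"cell_type": {"unicellular"}, "heterocysts": {"present"}},
            },
        )
        rules = [InferenceRule("cell_type", "unicellular", "heterocysts",
                               frozenset())]
        out = apply_inference_rules(ft, rules)
        assert out.values["x"]["heterocysts"] == frozenset()   # inferred absent
        assert out.values["y"]["heterocysts"] is None          # rule not triggered
        assert out.values["z"]["heterocysts"] == {"present"}   # known kept
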
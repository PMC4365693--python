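"""Rarefaction, new-genes-per-step conservation, and power-law fitting."""

import itertools

import numpy as np
import pytest

from cyanocore.accumulation import (
    NewGeneCurve,
    core_ratio,
    fit_power_law,
    new_genes_per_step,
    rarefy,
)
from cyanocore.clogs import ClogTable, classify_clogs
from cyanocore.synthetic import (
    PanGenomeSpec,
    gen_pan_genome,
    genome_ids,
    random_clog_table,
)


def brute_force_curve(table, statistic):
    """Exhaustive enumeration oracle: exact mean over all subsets per n."""
    genomes = sorted(table.genome_universe)
    sets = list(table.genome_sets().values())
    means = {}
    for n in range(1, len(genomes) + 1):
        vals = []
        for subset in itertools.combinations(genomes, n):
            s = set(subset)
            if statistic == "core":
                vals.append(sum(1 for gs in sets if s <= gs))
            else:
                vals.append(sum(1 for gs in sets if s & gs))
        means[n] = np.mean(vals)
    return means


class TestRarefy:
    def test_exhaustive_mode_matches_brute_force(self, rng):
        for _ in range(5):
            table = random_clog_table(6, 40, rng)
            for stat in ("core", "pan"):
                curve = rarefy(table, stat, exhaustive=True)
                oracle = brute_force_curve(table, stat)
                for n, mean in curve.mean().items():
                    assert mean == pytest.approx(oracle[n])

    def test_core_at_full_size_is_exact(self, toy_table):
        curve = rarefy(toy_table, "core", repetitions=10, seed=1)
        core = classify_clogs(toy_table).counts["core"]
        assert all(v == core for v in curve.replicates[5])

    def test_pan_at_one_is_single_genome_counts(self, toy_table):
        curve = rarefy(toy_table, "pan", repetitions=50, seed=1)
        allowed = {
            len(toy_table.clogs_of_genome(g)) for g in toy_table.genome_universe
        }
        assert set(curve.replicates[1]) <= allowed

    def test_nested_mode_monotone_per_replicate(self, rng):
        table = random_clog_table(7, 50, rng)
        core = rarefy(table, "core", repetitions=20, seed=3, nested=True)
        pan = rarefy(table, "pan", repetitions=20, seed=3, nested=True)
        for r in range(20):
            cvals = [core.replicates[n][r] for n in range(1, 8)]
            pvals = [pan.replicates[n][r] for n in range(1, 8)]
            assert all(a >= b for a, b in zip(cvals, cvals[1:]))
            assert all(a <= b for a, b in zip(pvals, pvals[1:]))

    def test_identical_seed_identical_output(self, toy_table):
        a = rarefy(toy_table, "pan", repetitions=30, seed=7)
        b = rarefy(toy_table, "pan", repetitions=30, seed=7)
        for n in a.replicates:
            assert np.array_equal(a.replicates[n], b.replicates[n])

    def test_invalid_args(self, toy_table):
        with pytest.raises(ValueError):
            rarefy(toy_table, "core", repetitions=0)
        with pytest.raises(ValueError):
            rarefy(toy_table, "median")


class TestNewGenes:
    def test_disjoint_genomes_every_step_adds_own_count(self):
        clogs = {}
        counts = {"A": 3, "B": 1, "C": 4}
        i = 0
        for g, k in counts.items():
            for _ in range(k):
                i += 1
                clogs[f"c{i}"] = [(g, f"g{i}")]
        table = ClogTable(clogs)
        curve = new_genes_per_step(table, permutations=20, seed=0)
        for n, vals in curve.per_step.items():
            assert set(vals) <= set(counts.values())

    def test_identical_genomes_add_nothing(self):
        table = ClogTable(
            {"c1": [("A", "a1"), ("B", "b1")], "c2": [("A", "a2"), ("B", "b2")]}
        )
        curve = new_genes_per_step(table, permutations=10, seed=0)
        assert all(v == 0 for v in curve.per_step[2])

    def test_per_ordering_conservation(self, rng):
        # pan(G) = pan(1) + sum of new(n) for every ordering
        table = random_clog_table(6, 50, rng)
        curve = new_genes_per_step(table, permutations=50, seed=5)
        pan_total = len(table)  # every CLOG touches some genome
        for r in range(50):
            total = curve.pan_first[r] + sum(
                curve.per_step[n][r] for n in curve.per_step
            )
            assert total == pan_total

    def test_means_match_exhaustive_orderings(self):
        # G=5 toy table: MC over many permutations vs all 120 orderings
        rng = np.random.default_rng(11)
        table = random_clog_table(5, 25, rng)
        genomes = sorted(table.genome_universe)
        sets = list(table.genome_sets().values())
        exact = {n: [] for n in range(2, 6)}
        for order in itertools.permutations(genomes):
            covered = set()
            prev = None
            for n, g in enumerate(order, start=1):
                cur = sum(1 for gs in sets if gs & set(order[:n]))
                if n >= 2:
                    exact[n].append(cur - prev)
                prev = cur
        curve = new_genes_per_step(table, permutations=3000, seed=2)
        for n in range(2, 6):
            assert curve.mean()[n] == pytest.approx(np.mean(exact[n]), abs=0.15)


class TestPowerLaw:
    def test_exact_closed_form_recovery(self):
        ns = np.arange(2, 21)
        vals = {int(n): np.array([100.0 * n ** -0.5]) for n in ns}
        curve = NewGeneCurve(per_step=vals, pan_first=np.array([0]),
                             permutations=1, seed=0)
        fit = fit_power_law(curve, bootstrap=0)
        assert fit.alpha == pytest.approx(0.5, abs=1e-9)
        assert fit.kappa == pytest.approx(100.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.is_open

    def test_closed_pangenome_alpha_above_one(self):
        ns = np.arange(2, 21)
        vals = {int(n): np.array([500.0 * n ** -1.5]) for n in ns}
        curve = NewGeneCurve(per_step=vals, pan_first=np.array([0]),
                             permutations=1, seed=0)
        fit = fit_power_law(curve, bootstrap=0)
        assert fit.alpha == pytest.approx(1.5, abs=1e-9)
        assert not fit.is_open

    def test_nonpositive_points_dropped(self):
        vals = {2: np.array([10.0]), 3: np.array([0.0]), 4: np.array([5.0]),
                5: np.array([4.0]), 6: np.array([3.5])}
        curve = NewGeneCurve(per_step=vals, pan_first=np.array([0]),
                             permutations=1, seed=0)
        fit = fit_power_law(curve, bootstrap=0)
        assert fit.dropped_points == [3]

    def test_too_few_points_rejected(self):
        vals = {2: np.array([10.0]), 3: np.array([8.0])}
        curve = NewGeneCurve(per_step=vals, pan_first=np.array([0]),
                             permutations=1, seed=0)
        with pytest.raises(ValueError):
            fit_power_law(curve, bootstrap=0)

    def test_bootstrap_sd_nonnegative_and_deterministic(self, rng):
        table = random_clog_table(10, 100, rng)
        curve = new_genes_per_step(table, permutations=50, seed=1)
        f1 = fit_power_law(curve, bootstrap=50, seed=9)
        f2 = fit_power_law(curve, bootstrap=50, seed=9)
        assert f1.alpha_sd >= 0
        assert f1.alpha == f2.alpha and f1.alpha_sd == f2.alpha_sd


class TestCoreRatio:
    def test_full_universe_ratio_is_one(self, toy_table):
        curve = rarefy(toy_table, "core", exhaustive=True)
        assert core_ratio(toy_table, toy_table.genome_universe, curve) == \
            pytest.approx(1.0)

    def test_planted_clade_core_enrichment(self):
        # clade {A,B,C} shares 5 extra CLOGs beyond the 4 global core CLOGs
        genomes = genome_ids(6)
        clade = set(genomes[:3])
        clogs = {}
        for i in range(4):
            clogs[f"core{i}"] = [(g, f"c{i}{g}") for g in genomes]
        for i in range(5):
            clogs[f"clade{i}"] = [(g, f"x{i}{g}") for g in sorted(clade)]
        table = ClogTable(clogs, genome_universe=genomes)
        curve = rarefy(table, "core", exhaustive=True)
        expected_mean = curve.mean(3)
        ratio = core_ratio(table, clade, curve)
        assert ratio == pytest.approx(9 / expected_mean)
        assert ratio > 1

    def test_small_clade_rejected(self, toy_table):
        curve = rarefy(toy_table, "core", exhaustive=True)
        with pytest.raises(ValueError):
            core_ratio(toy_table, {"A"}, curve)
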
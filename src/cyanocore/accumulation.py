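"""Core/pan-genome rarefaction and open-pangenome power-law fitting.

Rarefaction repeatedly draws random genome subsets of every size n and
records the core (CLOGs covering all sampled genomes) and pan (CLOGs touching
any sampled genome) sizes.  The growth of the pan-genome is summarized by the
Tettelin-style power law for the mean number of new CLOGs contributed by the
n-th genome, new(n) = kappa * n^(-alpha): for alpha <= 1 the pan-genome is
open (unbounded growth), only alpha > 1 gives a finite limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clogs import ClogTable

__all__ = [
    "RarefactionCurve",
    "PowerLawFit",
    "rarefy",
    "new_genes_per_step",
    "fit_power_law",
    "core_ratio",
]


@dataclass
class RarefactionCurve:
    statistic: str                     # "core" or "pan"
    replicates: dict[int, np.ndarray]  # n -> replicate values
    repetitions: int
    seed: int

    def mean(self, n: int | None = None):
        if n is not None:
            return float(np.mean(self.replicates[n]))
        return {k: float(np.mean(v)) for k, v in self.replicates.items()}

    def five_number_summary(self) -> dict[int, tuple[float, float, float, float, float]]:
        """Box-plot summaries (min, Q1, median, Q3, max) per subset size."""
        out = {}
        for n, v in self.replicates.items():
            q = np.percentile(v, [0, 25, 50, 75, 100])
            out[n] = tuple(float(x) for x in q)
        return out


@dataclass
class NewGeneCurve:
    """Newly added CLOGs at each genome-addition step, over P random orderings."""

    per_step: dict[int, np.ndarray]  # n (2..G) -> new-CLOG counts per ordering
    pan_first: np.ndarray            # pan size of each ordering's first genome
    permutations: int
    seed: int

    def mean(self) -> dict[int, float]:
        return {n: float(np.mean(v)) for n, v in self.per_step.items()}

    def sd(self) -> dict[int, float]:
        return {n: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                for n, v in self.per_step.items()}


@dataclass
class PowerLawFit:
    alpha: float
    kappa: float
    alpha_sd: float
    n_range: tuple[int, int]
    r_squared: float
    dropped_points: list[int] = field(default_factory=list)

    @property
    def is_open(self) -> bool:
        """Open pan-genome: growth never levels off unless alpha > 1."""
        return self.alpha <= 1.0


def _presence_matrix(table: ClogTable):
    df = table.presence()
    return df.values, list(df.columns)


def rarefy(
    table: ClogTable,
    statistic: str = "core",
    repetitions: int = 1000,
    seed: int = 0,
    nested: bool = False,
    exhaustive: bool = False,
) -> RarefactionCurve:
    """Rarefaction curve by repeated uniform random genome subsampling.

    For each subset size n in 1..G, draws ``repetitions`` subsets without
    replacement and records core(n) or pan(n).  With ``nested=True`` each
    replicate is one random genome ordering and subsets are its prefixes, so
    core is non-increasing and pan non-decreasing along each replicate.
    With ``exhaustive=True`` every distinct subset is evaluated exactly once
    (feasible for small G; repetitions and seed are ignored).
    """
    if statistic not in ("core", "pan"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    mat, genomes = _presence_matrix(table)
    G = len(genomes)
    if G == 0:
        raise ValueError("genome universe is empty")
    if exhaustive:
        import itertools

        reps = {}
        for n in range(1, G + 1):
            vals = []
            for idx in itertools.combinations(range(G), n):
                cols = mat[:, list(idx)]
                vals.append(
                    int(cols.all(axis=1).sum()) if statistic == "core"
                    else int(cols.any(axis=1).sum())
                )
            reps[n] = np.array(vals)
        return RarefactionCurve(
            statistic=statistic, replicates=reps,
            repetitions=0, seed=seed,
        )
    rng = np.random.default_rng(seed)
    reps: dict[int, list[int]] = {n: [] for n in range(1, G + 1)}
    for _ in range(repetitions):
        if nested:
            order = rng.permutation(G)
            for n in range(1, G + 1):
                cols = mat[:, order[:n]]
                val = int(cols.all(axis=1).sum()) if statistic == "core" \
                    else int(cols.any(axis=1).sum())
                reps[n].append(val)
        else:
            for n in range(1, G + 1):
                idx = rng.choice(G, size=n, replace=False)
                cols = mat[:, idx]
                val = int(cols.all(axis=1).sum()) if statistic == "core" \
                    else int(cols.any(axis=1).sum())
                reps[n].append(val)
    return RarefactionCurve(
        statistic=statistic,
        replicates={n: np.array(v) for n, v in reps.items()},
        repetitions=repetitions,
        seed=seed,
    )


def new_genes_per_step(
    table: ClogTable, permutations: int = 200, seed: int = 0
) -> NewGeneCurve:
    """New CLOGs contributed by the n-th genome over random orderings.

    For each random genome ordering, new(n) = pan(first n) - pan(first n-1).
    The per-ordering conservation pan(G) = pan(1) + sum new(n) holds exactly.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    mat, genomes = _presence_matrix(table)
    G = len(genomes)
    rng = np.random.default_rng(seed)
    per_step: dict[int, list[int]] = {n: [] for n in range(2, G + 1)}
    pan_first = []
    for _ in range(permutations):
        order = rng.permutation(G)
        covered = mat[:, order[0]].copy()
        pan_first.append(int(covered.sum()))
        prev = int(covered.sum())
        for n in range(2, G + 1):
            covered |= mat[:, order[n - 1]]
            cur = int(covered.sum())
            per_step[n].append(cur - prev)
            prev = cur
    return NewGeneCurve(
        per_step={n: np.array(v) for n, v in per_step.items()},
        pan_first=np.array(pan_first),
        permutations=permutations,
        seed=seed,
    )


def fit_power_law(
    new_curve: NewGeneCurve,
    n_min: int = 2,
    bootstrap: int = 100,
    seed: int = 0,
) -> PowerLawFit:
    """Fit mean new(n) = kappa * n^(-alpha) by log-log least squares.

    Points with non-positive mean are dropped (with a record); the spread of
    alpha is estimated by bootstrap resampling of the per-step replicate
    values (``bootstrap`` refits).
    """
    means = new_curve.mean()
    ns, ys, dropped = [], [], []
    for n in sorted(means):
        if n < n_min:
            continue
        if means[n] <= 0:
            dropped.append(n)
            continue
        ns.append(n)
        ys.append(means[n])
    if len(ns) < 3:
        raise ValueError(f"power-law fit needs >= 3 positive points, got {len(ns)}")
    logn = np.log(np.array(ns, dtype=float))
    logy = np.log(np.array(ys, dtype=float))
    res = stats.linregress(logn, logy)
    alpha = -res.slope
    kappa = float(np.exp(res.intercept))

    rng = np.random.default_rng(seed)
    alphas = []
    for _ in range(bootstrap):
        by = []
        for n in ns:
            v = new_curve.per_step[n]
            m = float(np.mean(rng.choice(v, size=len(v), replace=True)))
            by.append(m)
        by = np.array(by)
        ok = by > 0
        if ok.sum() < 3:
            continue
        b = stats.linregress(logn[ok], np.log(by[ok]))
        alphas.append(-b.slope)
    alpha_sd = float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0
    return PowerLawFit(
        alpha=float(alpha),
        kappa=kappa,
        alpha_sd=alpha_sd,
        n_range=(ns[0], ns[-1]),
        r_squared=float(res.rvalue**2),
        dropped_points=dropped,
    )


def core_ratio(
    table: ClogTable, clade: set[str], curve: RarefactionCurve
) -> float:
    """Observed clade core size over the expected core size at |clade| genomes.

    The expectation is the mean core replicate of the rarefaction curve at
    n = |clade|; a ratio well above 1 marks a clade sharing many more genes
    than a random strain sample of the same size would.
    """
    if curve.statistic != "core":
        raise ValueError("core_ratio needs a core rarefaction curve")
    clade = set(clade)
    if len(clade) < 2:
        raise ValueError("clade must contain >= 2 genomes")
    if not clade <= table.genome_universe:
        raise ValueError("clade not contained in the genome universe")
    sub = table.restrict(clade)
    from .clogs import classify_clogs

    observed = classify_clogs(sub).counts["core"]
    expected = curve.mean(len(clade))
    if expected == 0:
        raise ValueError("expected core size is zero at this clade size")
    return observed / expected
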
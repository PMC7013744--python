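"""Genetic-algorithm wrapper for universal feature-subset selection.

Binary chromosomes over the candidate pool are evolved with roulette-wheel
selection, two-point crossover and bit-flip mutation.  A chromosome's
fitness is the sum of its per-setting cross-validated SVM accuracies minus
every pairwise squared accuracy difference — so a subset is rewarded both
for accuracy and for performing *consistently* across acquisition
settings.  An optional repair operator pins the subset cardinality at an
exact k (the 5/10/15-feature runs).  Features are z-scored beforehand so
large-ranged features do not dominate the kernel distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import GAParams, SVMConfig
from .svm import cross_validate_arrays
from .table import LabeledFeatureTable


# ---------------------------------------------------------------------------
# feature scaling (wrapper stage (i))

@dataclass
class ScaledTable:
    """A feature table after per-feature standardization.

    The means and sample SDs are learned on one split (the selection half)
    and re-applied verbatim to any other split.  Constant features map to
    0 and are flagged.
    """

    table: LabeledFeatureTable
    means: pd.Series
    sds: pd.Series
    constant_features: List[str]

    def apply(self, other: LabeledFeatureTable) -> "LabeledFeatureTable":
        """Re-apply the learned scaling to another table."""
        df = other.df.copy()
        for fid in other.feature_columns:
            sd = self.sds[fid]
            df[fid] = 0.0 if sd == 0 else (df[fid] - self.means[fid]) / sd
        return LabeledFeatureTable(df)


def scale_features(table: LabeledFeatureTable) -> ScaledTable:
    """Per-feature z-transform (sample SD); constant columns become 0."""
    df = table.df.copy()
    means = {}
    sds = {}
    constant = []
    for fid in table.feature_columns:
        x = df[fid].to_numpy(dtype=float)
        mu = float(x.mean())
        sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        means[fid], sds[fid] = mu, sd
        if sd == 0:
            constant.append(fid)
            df[fid] = 0.0
        else:
            df[fid] = (x - mu) / sd
    return ScaledTable(
        table=LabeledFeatureTable(df),
        means=pd.Series(means),
        sds=pd.Series(sds),
        constant_features=constant,
    )


# ---------------------------------------------------------------------------
# fitness

def fitness(accuracies: Sequence[float]) -> float:
    """Sum of accuracies minus all pairwise squared differences.

    Permutation-invariant; for a fixed accuracy total it is maximal when
    all settings agree, which is exactly the universality the selection
    is after.
    """
    accs = [float(a) for a in accuracies]
    if not accs:
        raise ValueError("need at least one accuracy")
    for a in accs:
        if not 0.0 <= a <= 1.0:
            raise ValueError("accuracies must lie in [0, 1]")
    penalty = sum((a - b) ** 2 for a, b in combinations(accs, 2))
    return float(sum(accs) - penalty)


@dataclass
class FitnessReport:
    """Per-setting accuracies and the scalar fitness of one chromosome."""

    bits: Tuple[int, ...]
    features: List[str]
    setting_accuracies: Dict[object, float]
    fitness: float

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "setting_accuracies": {str(k): v for k, v in self.setting_accuracies.items()},
            "fitness": self.fitness,
        }


class ChromosomeEvaluator:
    """Scores chromosomes by multi-setting cross-validated SVM accuracy.

    Results are cached by bit pattern: with a fixed fold seed the CV
    accuracy is a deterministic function of (setting, subset), so repeated
    chromosomes — frequent in small pools — cost nothing.
    """

    def __init__(
        self,
        table: LabeledFeatureTable,
        pool: Sequence[str],
        svm_config: SVMConfig | None = None,
    ):
        self.table = table
        self.pool = list(pool)
        self.svm_config = svm_config or SVMConfig()
        self.settings = table.settings
        self._cache: Dict[Tuple[int, ...], FitnessReport] = {}
        # pre-extracted per-setting arrays for speed
        self._data = {}
        for s in self.settings:
            X, y = table.matrix(setting_id=s, features=self.pool)
            self._data[s] = (X, y)

    def evaluate(self, bits: Sequence[int]) -> FitnessReport:
        key = tuple(int(b) for b in bits)
        if len(key) != len(self.pool):
            raise ValueError("chromosome length must equal the pool size")
        if sum(key) == 0:
            raise ValueError("chromosome selects no features")
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        cols = np.flatnonzero(np.asarray(key))
        accs = {}
        for s in self.settings:
            X, y = self._data[s]
            accs[s] = cross_validate_arrays(X[:, cols], y, self.svm_config).mean_accuracy
        report = FitnessReport(
            bits=key,
            features=[self.pool[i] for i in cols],
            setting_accuracies=accs,
            fitness=fitness(list(accs.values())),
        )
        self._cache[key] = report
        return report


# ---------------------------------------------------------------------------
# genetic operators

def roulette_select(
    fitnesses: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices sampled with probability proportional to shifted fitness.

    Fitness is shifted so its minimum is >= 0 (plus a small epsilon);
    an all-zero total falls back to uniform sampling.  With replacement.
    """
    f = np.asarray(fitnesses, dtype=float)
    shifted = f - min(f.min(), 0.0)
    total = shifted.sum()
    if total <= 0:
        p = np.full(len(f), 1.0 / len(f))
    else:
        p = shifted / total
    return rng.choice(len(f), size=count, replace=True, p=p)


def two_point_crossover(
    a: np.ndarray, b: np.ndarray, probability: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Swap the segment between two distinct cut points, with probability."""
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("parents must share a length >= 3")
    a, b = a.copy(), b.copy()
    if rng.random() < probability:
        c1, c2 = sorted(rng.choice(np.arange(1, len(a)), size=2, replace=False))
        a[c1:c2], b[c1:c2] = b[c1:c2].copy(), a[c1:c2].copy()
    return a, b


def mutate(bits: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with the given probability."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    flips = rng.random(len(bits)) < rate
    return np.where(flips, 1 - bits, bits)


def repair(bits: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Force exactly k set bits, clearing/raising uniformly at random."""
    if k > len(bits):
        raise ValueError("cardinality exceeds chromosome length")
    bits = bits.copy()
    ones = np.flatnonzero(bits == 1)
    zeros = np.flatnonzero(bits == 0)
    if len(ones) > k:
        drop = rng.choice(ones, size=len(ones) - k, replace=False)
        bits[drop] = 0
    elif len(ones) < k:
        raise_ = rng.choice(zeros, size=k - len(ones), replace=False)
        bits[raise_] = 1
    return bits


# ---------------------------------------------------------------------------
# the generational loop

@dataclass
class GAResult:
    """Best chromosome found plus the per-generation fitness history."""

    best: FitnessReport
    history_best: List[float]
    history_mean: List[float]
    params: GAParams
    pool: List[str]

    def to_dict(self) -> dict:
        return {
            "best": self.best.to_dict(),
            "history_best": self.history_best,
            "history_mean": self.history_mean,
            "pool": self.pool,
            "rng_seed": self.params.rng_seed,
        }


def evolve(
    table: LabeledFeatureTable,
    pool: Sequence[str],
    params: GAParams | None = None,
    svm_config: SVMConfig | None = None,
    evaluator: ChromosomeEvaluator | None = None,
) -> GAResult:
    """Run the generational GA over the candidate pool.

    Selection -> two-point crossover -> mutation -> (repair) -> evaluation
    with 1-elitism, stopping at the configured generation count.  One
    seeded generator drives every stochastic step, so identical seeds
    give identical histories.
    """
    params = params or GAParams()
    pool = list(pool)
    if not pool:
        raise ValueError("candidate pool is empty")
    if evaluator is None:
        evaluator = ChromosomeEvaluator(table, pool, svm_config)
    rng = np.random.default_rng(params.rng_seed)
    F = len(pool)
    k = params.cardinality

    def legalize(bits: np.ndarray) -> np.ndarray:
        if k is not None:
            return repair(bits, k, rng)
        if bits.sum() == 0:  # an empty subset cannot be scored
            bits = bits.copy()
            bits[rng.integers(F)] = 1
        return bits

    population = [
        legalize(rng.integers(0, 2, size=F)) for _ in range(params.population_size)
    ]
    reports = [evaluator.evaluate(c) for c in population]
    best = max(reports, key=lambda r: r.fitness)
    history_best, history_mean = [], []

    for _ in range(params.generations):
        fits = np.array([r.fitness for r in reports])
        history_best.append(float(best.fitness))
        history_mean.append(float(fits.mean()))

        parents = roulette_select(fits, params.population_size, rng)
        children: List[np.ndarray] = []
        for i in range(0, params.population_size, 2):
            pa = population[parents[i]]
            pb = population[parents[(i + 1) % params.population_size]]
            ca, cb = two_point_crossover(pa, pb, params.crossover_probability, rng)
            children.extend([ca, cb])
        children = children[: params.population_size]
        children = [legalize(mutate(c, params.mutation_rate, rng)) for c in children]

        # elitism: the best-ever chromosome survives unchanged
        for e in range(min(params.elitism, len(children))):
            children[e] = np.asarray(best.bits)

        population = children
        reports = [evaluator.evaluate(c) for c in population]
        gen_best = max(reports, key=lambda r: r.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best

    history_best.append(float(best.fitness))
    history_mean.append(float(np.mean([r.fitness for r in reports])))
    return GAResult(
        best=best,
        history_best=history_best,
        history_mean=history_mean,
        params=params,
        pool=pool,
    )
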
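"""Reproducible study-condition experiments.

Each function sets up synthetic data at the study's conditions (four
acquisition settings, class separation of 2 within-class SDs, a few
hundred paired blocks per class per setting), runs one part of the
method, and returns the measured quantity.  One master seed drives every
stochastic component; per-run seeds are derived from it.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .config import GAParams, SVMConfig
from .ga import ChromosomeEvaluator, evolve, scale_features
from .pipeline import PipelineConfig, run_select, split_by_pair
from .simulate import TableGenSpec, generate_feature_table
from .svm import cross_validate_arrays
from .table import LabeledFeatureTable

PLANTED = ("F1", "F2", "F3")


def ga_recovery_experiment(
    master_seed: int,
    n_runs: int = 20,
    n_features: int = 20,
    n_per_class: int = 200,
    population: int = 30,
    generations: int = 20,
) -> Dict[str, float]:
    """Planted-subset recovery rate of the constrained GA.

    One 4-setting table with 3 planted universal features among
    ``n_features`` is drawn from the master seed; the GA (cardinality 3)
    is run ``n_runs`` times with per-run seeds driving initialization,
    the genetic operators and the CV fold assignment alike.  Recovery
    means the best-ever chromosome equals the planted set exactly.
    """
    spec = TableGenSpec(
        n_settings=4,
        n_per_class_per_setting=n_per_class,
        n_features=n_features,
        universal_informative=PLANTED,
        effect_size=2.0,
        seed=master_seed,
    )
    scaled = scale_features(generate_feature_table(spec)).table
    wins = 0
    for run in range(n_runs):
        run_seed = (master_seed + run) % 2**31
        svm = SVMConfig(folds=5, fold_seed=run_seed)
        params = GAParams(
            population_size=population,
            generations=generations,
            cardinality=len(PLANTED),
            rng_seed=run_seed,
        )
        result = evolve(scaled, scaled.feature_columns, params, svm)
        wins += set(result.best.features) == set(PLANTED)
    return {"recovery_rate": wins / n_runs, "n_runs": n_runs}


def consistency_preference_experiment(
    master_seed: int, n_runs: int = 20, n_per_class: int = 100
) -> Dict[str, float]:
    """How often the fitness ranks a universal subset above a
    setting-specific one of equal single-setting accuracy.

    Each run draws a fresh 4-setting table holding one universal pair of
    informative features and one pair informative only in setting 1, at
    the same effect size (so their accuracies match where both work).
    """
    wins = 0
    for run in range(n_runs):
        run_seed = (master_seed + run) % 2**31
        spec = TableGenSpec(
            n_settings=4,
            n_per_class_per_setting=n_per_class,
            n_features=8,
            universal_informative=("F1", "F2"),
            setting_specific_informative={1: ("F3", "F4")},
            effect_size=2.0,
            seed=run_seed,
        )
        scaled = scale_features(generate_feature_table(spec)).table
        ev = ChromosomeEvaluator(
            scaled, scaled.feature_columns, SVMConfig(folds=5, fold_seed=run_seed)
        )
        universal = ev.evaluate([1, 1, 0, 0, 0, 0, 0, 0])
        specific = ev.evaluate([0, 0, 1, 1, 0, 0, 0, 0])
        wins += universal.fitness > specific.fitness
    return {"preference_rate": wins / n_runs, "n_runs": n_runs}


def label_shuffle_experiment(master_seed: int, n: int = 400) -> float:
    """Mean CV accuracy on label-shuffled separable data (chance level)."""
    rng = np.random.default_rng(master_seed)
    X = np.vstack(
        [rng.normal(0.0, 1.0, size=(n // 2, 3)), rng.normal(10.0, 1.0, size=(n // 2, 3))]
    )
    y = rng.permutation(np.array([-1] * (n // 2) + [1] * (n // 2)))
    res = cross_validate_arrays(X, y, SVMConfig(folds=5, fold_seed=master_seed))
    return res.mean_accuracy


def determinism_and_leakage_experiment(master_seed: int) -> Dict[str, float]:
    """Identical seeds give identical reports; no pair crosses the split."""
    spec = TableGenSpec(
        n_settings=3,
        n_per_class_per_setting=60,
        n_features=10,
        universal_informative=("F1", "F2"),
        effect_size=2.0,
        seed=master_seed,
    )
    table = generate_feature_table(spec)
    config = PipelineConfig(
        svm=SVMConfig(folds=3, fold_seed=master_seed),
        ga=GAParams(population_size=12, generations=5, rng_seed=master_seed),
        filter_top_n=10,
        cardinalities=(2,),
        seed=master_seed,
    )
    r1 = run_select(table, config)
    r2 = run_select(table, config)
    sel, held = split_by_pair(table, 0.5, master_seed)
    crossings = len(set(sel.df["pair_id"]) & set(held.df["pair_id"]))
    return {
        "reports_identical": float(r1.to_dict() == r2.to_dict()),
        "pair_id_crossings": float(crossings),
    }
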
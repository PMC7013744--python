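"""End-to-end orchestration: extract -> filter -> select -> evaluate.

The feature table is split 50/50 by ``pair_id`` (stratified by class,
seeded) so that all settings of a physical block stay on one side of the
split; scaling parameters, filter scores and the GA search use only the
selection half, and the chosen subsets are then scored on the held-out
half.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .config import PipelineConfig
from .features import FEATURE_IDS, extract_all, feature_name
from .filters import build_candidate_pool
from .ga import ChromosomeEvaluator, GAParams, evolve, scale_features
from .image import tile_blocks
from .svm import cross_validate
from .table import LabeledFeatureTable


def run_extract(
    manifest: pd.DataFrame | str | Path,
    root: str | Path | None = None,
    config: PipelineConfig | None = None,
    block_size: int = 23,
) -> LabeledFeatureTable:
    """Tile every manifest image by its mask and extract the feature bank.

    The manifest needs columns ``sample_id, setting_id, pair_id, class,
    image, mask`` with image paths relative to ``root`` (or to the
    manifest's directory).
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        root = root if root is not None else path.parent
        manifest = pd.read_csv(path)
    root = Path(root) if root is not None else Path(".")
    rows = []
    for rec in manifest.to_dict("records"):
        image = np.asarray(Image.open(root / rec["image"]).convert("L"), dtype=np.int64)
        mask = np.asarray(Image.open(root / rec["mask"]).convert("L"))
        if mask.shape != image.shape:
            raise ValueError(
                f"mask {rec['mask']} shape {mask.shape} does not match image "
                f"{rec['image']} shape {image.shape}"
            )
        blocks = tile_blocks(
            image, mask, block_size=block_size, source_id=str(rec["sample_id"])
        )
        for blk in blocks:
            vec = extract_all(blk, config.matrix)
            suffix = f"_b{blk.block_row}_{blk.block_col}"
            rows.append(
                {
                    "sample_id": f"{rec['sample_id']}{suffix}",
                    "setting_id": rec["setting_id"],
                    "pair_id": f"{rec['pair_id']}{suffix}",
                    "class": rec["class"],
                    **dict(zip(FEATURE_IDS, vec)),
                }
            )
    if not rows:
        import warnings

        warnings.warn("no fully-masked blocks found; empty feature table")
        return None
    return LabeledFeatureTable(pd.DataFrame(rows))


def split_by_pair(
    table: LabeledFeatureTable, fraction: float = 0.5, seed: int = 0
) -> Tuple[LabeledFeatureTable, LabeledFeatureTable]:
    """Class-stratified split by pair_id; no pair crosses the boundary."""
    rng = np.random.default_rng(seed)
    pair_class = (
        table.df[["pair_id", "class"]].drop_duplicates("pair_id").set_index("pair_id")["class"]
    )
    selection_ids: List = []
    for cls in table.classes:
        ids = pair_class[pair_class == cls].index.to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_sel = int(round(len(ids) * fraction))
        selection_ids.extend(ids[:n_sel].tolist())
    selection = table.subset_pairs(selection_ids)
    heldout = table.subset_pairs(set(pair_class.index) - set(selection_ids))
    return selection, heldout


@dataclass
class RunReport:
    """Everything one selection run produced, recomputable from its parts."""

    selected: Dict[int, List[str]]  # cardinality -> feature ids
    selection_cv_accuracies: Dict[int, Dict[object, float]]
    heldout_accuracies: Dict[int, Dict[object, float]]
    fitness: Dict[int, float]
    pool: List[str]
    pool_fallback: bool
    config_hash: str
    seed: int
    history: Dict[int, List[float]] = field(default_factory=dict)

    def summary(self, cardinality: int) -> dict:
        accs = list(self.heldout_accuracies[cardinality].values())
        return {
            "mean": float(np.mean(accs)),
            "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "max": float(np.max(accs)),
            "min": float(np.min(accs)),
        }

    def to_dict(self) -> dict:
        return {
            "selected": {str(k): v for k, v in self.selected.items()},
            "selection_cv_accuracies": {
                str(k): {str(s): a for s, a in v.items()}
                for k, v in self.selection_cv_accuracies.items()
            },
            "heldout_accuracies": {
                str(k): {str(s): a for s, a in v.items()}
                for k, v in self.heldout_accuracies.items()
            },
            "fitness": {str(k): v for k, v in self.fitness.items()},
            "pool": self.pool,
            "pool_fallback": self.pool_fallback,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }


def run_select(
    table: LabeledFeatureTable, config: PipelineConfig | None = None
) -> RunReport:
    """Full selection run: split, scale, filter, GA per cardinality, evaluate."""
    config = config or PipelineConfig()
    config_hash = hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]

    selection, heldout = split_by_pair(table, config.split_fraction, config.seed)
    assert not set(selection.df["pair_id"]) & set(heldout.df["pair_id"])

    scaled = scale_features(selection)
    scaled_heldout = scaled.apply(heldout)

    pool = build_candidate_pool(
        scaled.table,
        top_n=min(config.filter_top_n, len(table.feature_columns)),
        svm_config=config.svm,
        pool_floor=config.filter_pool_floor,
    )

    selected: Dict[int, List[str]] = {}
    sel_accs: Dict[int, Dict[object, float]] = {}
    held_accs: Dict[int, Dict[object, float]] = {}
    fits: Dict[int, float] = {}
    history: Dict[int, List[float]] = {}
    evaluator = ChromosomeEvaluator(scaled.table, pool.selected, config.svm)
    for k in config.cardinalities:
        params = GAParams(
            population_size=config.ga.population_size,
            generations=config.ga.generations,
            crossover_probability=config.ga.crossover_probability,
            mutation_rate=config.ga.mutation_rate,
            cardinality=min(k, len(pool.selected)),
            elitism=config.ga.elitism,
            rng_seed=config.ga.rng_seed + k,
        )
        result = evolve(scaled.table, pool.selected, params, config.svm, evaluator)
        feats = result.best.features
        selected[k] = feats
        sel_accs[k] = result.best.setting_accuracies
        fits[k] = result.best.fitness
        history[k] = result.history_best
        held_accs[k] = {
            s: cross_validate(scaled_heldout, feats, config.svm, setting_id=s).mean_accuracy
            for s in scaled_heldout.settings
        }
    return RunReport(
        selected=selected,
        selection_cv_accuracies=sel_accs,
        heldout_accuracies=held_accs,
        fitness=fits,
        pool=pool.selected,
        pool_fallback=pool.fallback_used,
        config_hash=config_hash,
        seed=config.seed,
    )


def run_report(report: RunReport) -> str:
    """Human-readable summary: feature names plus mean/SD per cardinality."""
    lines = []
    for k in sorted(report.selected):
        feats = report.selected[k]
        if not feats:
            lines.append(f"[k={k}] no features selected")
            continue
        names = ", ".join(f"{f} ({feature_name(f)})" for f in feats)
        lines.append(f"[k={k}] selected: {names}")
        for s, a in report.heldout_accuracies[k].items():
            lines.append(f"  setting {s}: held-out accuracy {a:.4f}")
        summ = report.summary(k)
        lines.append(
            f"  mean {summ['mean']:.4f}  sd {summ['sd']:.4f}  "
            f"max {summ['max']:.4f}  min {summ['min']:.4f}"
        )
    return "\n".join(lines)
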
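"""Synthetic paired multi-setting data.

Two generators stand in for the private clinical dataset:

* :func:`generate_feature_table` draws feature tables directly, with
  planted structure — *universal* informative features whose class means
  separate in every acquisition setting, optional *setting-specific*
  features informative in a single setting, and pure-noise columns.  The
  same physical block observed under different settings shares an
  additive latent pair effect, which is what makes the paired
  correlation score informative.

* :func:`generate_texture_dataset` draws two-class textured image
  blocks: class-conditional stationary random fields (white noise
  smoothed with a class-specific kernel), with one base field per pair
  transformed by each setting's monotone gain/dynamic-range-compression
  map and quantized to 8 bits.

Neither generator models acquisition physics (speckle, attenuation); the
selection method consumes only feature statistics, and monotone
intensity maps are the minimal stand-in for distinct scanner settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .table import LabeledFeatureTable

# Default per-setting monotone intensity maps (gain, compression exponent),
# echoing the gain / dynamic-range vocabulary of scanner presets.
DEFAULT_SETTING_TRANSFORMS: Tuple[Tuple[float, float], ...] = (
    (1.00, 1.00),
    (1.15, 0.80),
    (0.90, 1.20),
    (1.05, 0.65),
)

#: mild per-setting affine maps applied to every feature column
DEFAULT_FEATURE_TRANSFORMS: Tuple[Tuple[float, float], ...] = (
    (1.0, 0.0),
    (1.2, 0.5),
    (0.9, -0.3),
    (1.1, 0.2),
)


@dataclass
class TableGenSpec:
    """Recipe for a planted-structure feature table.

    The study design is four acquisition settings with roughly 500 blocks
    per class per setting, paired across settings.  ``effect_size`` is the
    class-mean separation in within-class SD units; ``cross_setting_noise``
    is the SD of the per-setting perturbation (the remaining within-class
    variance is the latent pair effect shared across settings, so total
    within-class variance is 1).
    """

    n_settings: int = 4
    n_per_class_per_setting: int = 500
    n_features: int = 126
    universal_informative: Tuple[str, ...] = ("F1", "F2", "F3")
    setting_specific_informative: Optional[Dict[int, Tuple[str, ...]]] = None
    effect_size: float = 2.0
    cross_setting_noise: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_settings < 2 or self.n_per_class_per_setting < 2:
            raise ValueError("need >= 2 settings and >= 2 samples per class")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.cross_setting_noise <= 1.0:
            raise ValueError("cross_setting_noise must lie in (0, 1]")
        specific = set()
        for feats in (self.setting_specific_informative or {}).values():
            for f in feats:
                if f in specific:
                    raise ValueError("setting-specific informative sets overlap")
                specific.add(f)
        if specific & set(self.universal_informative):
            raise ValueError("universal and setting-specific informative sets overlap")


def generate_feature_table(spec: TableGenSpec) -> LabeledFeatureTable:
    """Draw a paired multi-setting table with planted informative columns."""
    rng = np.random.default_rng(spec.seed)
    fids = [f"F{i}" for i in range(1, spec.n_features + 1)]
    settings = list(range(1, spec.n_settings + 1))
    classes = ("BM", "IDC")  # negative, positive
    n_pairs = spec.n_per_class_per_setting  # per class

    sigma_e = spec.cross_setting_noise
    sigma_b = float(np.sqrt(max(1.0 - sigma_e**2, 0.0)))
    specific = {
        s: set(feats)
        for s, feats in (spec.setting_specific_informative or {}).items()
    }
    universal = set(spec.universal_informative)
    unknown = (universal | set().union(*specific.values()) if specific else universal) - set(fids)
    if unknown:
        raise ValueError(f"informative features outside the table: {sorted(unknown)}")

    rows = []
    pair_counter = 0
    for cls_idx, cls in enumerate(classes):
        sign = 1.0 if cls == "IDC" else -1.0
        # latent pair effects, shared across settings: (n_pairs, n_features)
        b = rng.normal(0.0, sigma_b, size=(n_pairs, spec.n_features))
        for s_idx, s in enumerate(settings):
            eps = rng.normal(0.0, sigma_e, size=(n_pairs, spec.n_features))
            x = b + eps
            for j, fid in enumerate(fids):
                informative = fid in universal or fid in specific.get(s, set())
                if informative:
                    x[:, j] += sign * spec.effect_size / 2.0
            gain, offset = DEFAULT_FEATURE_TRANSFORMS[
                s_idx % len(DEFAULT_FEATURE_TRANSFORMS)
            ]
            x = gain * x + offset
            for p in range(n_pairs):
                pair_id = pair_counter + p
                rows.append(
                    {
                        "sample_id": f"syn{pair_id}s{s}",
                        "setting_id": s,
                        "pair_id": pair_id,
                        "class": cls,
                        **dict(zip(fids, x[p])),
                    }
                )
        pair_counter += n_pairs
    df = pd.DataFrame(rows)
    return LabeledFeatureTable(df)


# ---------------------------------------------------------------------------
# textured image blocks


@dataclass
class ImageGenSpec:
    """Recipe for paired two-class textured image blocks.

    Class texture differs by the width of the Gaussian kernel smoothing a
    white-noise field (coarser speckle for the wider kernel); each
    setting applies its own monotone gain/compression intensity map to
    the shared base field before 8-bit quantization.
    """

    block_size: int = 23
    class_smoothing: Tuple[float, float] = (1.0, 3.0)
    setting_transforms: Tuple[Tuple[float, float], ...] = DEFAULT_SETTING_TRANSFORMS
    n_blocks_per_class: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size < 8:
            raise ValueError("block_size must be >= 8")
        if any(g <= 0 for g, _ in self.setting_transforms):
            raise ValueError("gains must be positive")


@dataclass
class TextureBlockRecord:
    """One generated block under one setting."""

    sample_id: str
    setting_id: int
    pair_id: int
    label: str
    pixels: np.ndarray  # uint8
    mask: np.ndarray  # bool, all True


@dataclass
class TextureDataset:
    records: List[TextureBlockRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _setting_map(u: np.ndarray, gain: float, compression: float) -> np.ndarray:
    """Monotone intensity map: gamma-style compression then gain, to 8 bits."""
    v = np.clip(gain * np.power(np.clip(u, 0.0, 1.0), compression), 0.0, 1.0)
    return np.round(v * 255.0).astype(np.uint8)


def generate_texture_dataset(spec: ImageGenSpec) -> TextureDataset:
    """Class-conditional smoothed random fields, paired across settings."""
    rng = np.random.default_rng(spec.seed)
    ds = TextureDataset()
    pair_id = 0
    for label, sigma in zip(("BM", "IDC"), spec.class_smoothing):
        for _ in range(spec.n_blocks_per_class):
            base = rng.normal(size=(spec.block_size, spec.block_size))
            base = gaussian_filter(base, sigma=sigma, mode="reflect")
            lo, hi = base.min(), base.max()
            u = (base - lo) / (hi - lo) if hi > lo else np.zeros_like(base)
            for s_idx, (gain, comp) in enumerate(spec.setting_transforms, start=1):
                pixels = _setting_map(u, gain, comp)
                ds.records.append(
                    TextureBlockRecord(
                        sample_id=f"img{pair_id}s{s_idx}",
                        setting_id=s_idx,
                        pair_id=pair_id,
                        label=label,
                        pixels=pixels,
                        mask=np.ones_like(pixels, dtype=bool),
                    )
                )
            pair_id += 1
    return ds


def write_fixtures(dataset: TextureDataset, directory: str | Path) -> pd.DataFrame:
    """Write blocks + masks as PNGs with a CSV manifest; returns the manifest.

    The layout round-trips losslessly through the pipeline reader:
    columns ``sample_id, setting_id, pair_id, class, image, mask`` with
    paths relative to the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.records:
        img_name = f"{rec.sample_id}.png"
        mask_name = f"{rec.sample_id}_mask.png"
        try:
            Image.fromarray(rec.pixels, mode="L").save(directory / img_name)
            Image.fromarray(
                (rec.mask.astype(np.uint8) * 255), mode="L"
            ).save(directory / mask_name)
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"writing fixture under {directory}: {exc}") from exc
        rows.append(
            {
                "sample_id": rec.sample_id,
                "setting_id": rec.setting_id,
                "pair_id": rec.pair_id,
                "class": rec.label,
                "image": img_name,
                "mask": mask_name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
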
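"""Labeled feature tables.

A table holds one row per (sample, acquisition setting): identifier
columns ``sample_id``, ``setting_id``, ``pair_id``, ``class`` and the
feature columns ``F1..Fk``.  ``pair_id`` links the same physical ROI
block across the settings, which is what makes the paired correlation
score and the leakage-free 50/50 split possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

ID_COLUMNS = ("sample_id", "setting_id", "pair_id", "class")


@dataclass
class LabeledFeatureTable:
    """samples x features with class label, setting id and pairing id."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if not self.feature_columns:
            raise ValueError("feature table has no feature columns")
        dup = self.df.duplicated(subset=["setting_id", "pair_id"])
        if dup.any():
            raise ValueError("pair_id must occur at most once per setting")

    @property
    def feature_columns(self) -> List[str]:
        return [c for c in self.df.columns if c not in ID_COLUMNS]

    @property
    def settings(self) -> List:
        return sorted(self.df["setting_id"].unique().tolist())

    @property
    def classes(self) -> List:
        return sorted(self.df["class"].unique().tolist())

    @property
    def n_settings(self) -> int:
        return len(self.settings)

    def setting(self, setting_id) -> pd.DataFrame:
        return self.df[self.df["setting_id"] == setting_id]

    def feature(self, fid: str) -> pd.Series:
        return self.df[fid]

    def matrix(self, setting_id=None, features: Sequence[str] | None = None):
        """(X, y) arrays for one setting (or pooled), y in {-1, +1}."""
        sub = self.df if setting_id is None else self.setting(setting_id)
        features = list(features) if features is not None else self.feature_columns
        X = sub[features].to_numpy(dtype=float)
        classes = self.classes
        if len(classes) != 2:
            raise ValueError("expected exactly two classes")
        y = np.where(sub["class"].to_numpy() == classes[1], 1, -1)
        return X, y

    def subset_pairs(self, pair_ids) -> "LabeledFeatureTable":
        keep = self.df["pair_id"].isin(set(pair_ids))
        return LabeledFeatureTable(self.df[keep].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledFeatureTable":
        return cls(pd.read_csv(path, comment="#"))
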
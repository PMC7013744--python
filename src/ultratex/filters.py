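"""Filter-stage feature scoring across acquisition settings.

Three classifier-independent scores rate every feature on a multi-setting
table:

* an augmented Sorensen-Dice (Fisher-style) ratio — between-setting
  squared mean deviation over the summed within-setting sample variances;
* a t-score — the absolute two-sample Welch statistic per setting,
  aggregated as (sum over settings) / (S * SD over settings), so features
  that discriminate *consistently* score highest;
* a paired Pearson score — per-feature correlation between settings over
  pair-matched blocks, averaged per setting and aggregated the same way.

Features are ranked per metric; the candidate pool passed to the wrapper
stage is the intersection of the aggregate-rank list with a
single-feature classifier-accuracy list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from .config import SVMConfig
from .table import LabeledFeatureTable

#: guard for dispersion denominators that may legitimately vanish
EPSILON = 1e-12


def dice_score(table: LabeledFeatureTable, fid: str, by: str = "setting_id") -> float:
    """Augmented Sorensen-Dice ratio: between-group squared mean deviation
    over summed within-group sample variances (>= 0).

    Groups are the acquisition settings by default; ``by="class"`` gives
    the classic two-class Fisher-discriminant orientation instead.
    """
    values = table.df[fid].to_numpy(dtype=float)
    grand = values.mean()
    num = 0.0
    den = 0.0
    for _, sub in table.df.groupby(by):
        x = sub[fid].to_numpy(dtype=float)
        num += (x.mean() - grand) ** 2
        den += x.var(ddof=1)
    return float(num / max(den, EPSILON))


def ttest_score_setting(
    table: LabeledFeatureTable, fid: str, setting_id, form: str = "standard"
) -> float:
    """Absolute Welch statistic of one feature within one setting.

    ``form="squared_numerator"`` squares the mean difference instead of
    taking its absolute value (an alternative reading of the score).
    """
    sub = table.setting(setting_id)
    neg_cls, pos_cls = table.classes
    pos = sub[sub["class"] == pos_cls][fid].to_numpy(dtype=float)
    neg = sub[sub["class"] == neg_cls][fid].to_numpy(dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("both classes need >= 2 samples in the setting")
    se = np.sqrt(pos.var(ddof=1) / len(pos) + neg.var(ddof=1) / len(neg))
    diff = pos.mean() - neg.mean()
    num = diff * diff if form == "squared_numerator" else abs(diff)
    return float(num / max(se, EPSILON))


def ttest_score(
    table: LabeledFeatureTable, fid: str, form: str = "standard"
) -> tuple[float, bool]:
    """Aggregate t-score across settings; returns (score, degenerate flag).

    sum(T_j) / (S * SD(T_1..T_S)) with the sample SD; a zero SD (perfectly
    consistent per-setting scores) is epsilon-guarded and flagged.
    """
    per = [ttest_score_setting(table, fid, s, form) for s in table.settings]
    s = len(per)
    sd = float(np.std(per, ddof=1)) if s > 1 else 0.0
    degenerate = sd < EPSILON
    return float(np.sum(per) / (s * max(sd, EPSILON))), degenerate


def pearson_pairwise(
    table: LabeledFeatureTable, fid: str, setting_i, setting_j
) -> float:
    """Pearson correlation of one feature between two settings.

    Matching is by ``pair_id``; rows without a complete pair across the
    two settings are dropped.  Zero variance on either side yields 0.
    """
    a = table.setting(setting_i).set_index("pair_id")[fid]
    b = table.setting(setting_j).set_index("pair_id")[fid]
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("need >= 2 matched pairs between the settings")
    x = a.loc[common].to_numpy(dtype=float)
    y = b.loc[common].to_numpy(dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    den = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if den < EPSILON:
        return 0.0
    return float(np.clip(np.sum(xc * yc) / den, -1.0, 1.0))


def pearson_setting(table: LabeledFeatureTable, fid: str, setting_i) -> float:
    """Mean absolute pairwise correlation of one setting with the others."""
    others = [s for s in table.settings if s != setting_i]
    if not others:
        raise ValueError("need >= 2 settings")
    return float(
        np.mean([abs(pearson_pairwise(table, fid, setting_i, j)) for j in others])
    )


def pearson_score(table: LabeledFeatureTable, fid: str) -> tuple[float, bool]:
    """Aggregate paired-correlation score; returns (score, degenerate flag)."""
    per = [pearson_setting(table, fid, s) for s in table.settings]
    s = len(per)
    sd = float(np.std(per, ddof=1)) if s > 1 else 0.0
    degenerate = sd < EPSILON
    return float(np.sum(per) / (s * max(sd, EPSILON))), degenerate


def score_table(
    table: LabeledFeatureTable, ttest_form: str = "standard", dice_by: str = "class"
) -> pd.DataFrame:
    """All three scores and their descending ranks for every feature.

    The ranking uses the class-discriminative orientation of the Dice
    ratio by default (groups = the two diagnosis classes), since the
    filter's job is to drop features that carry no class signal; pass
    ``dice_by="setting_id"`` for the between-setting orientation.
    """
    rows = []
    for fid in table.feature_columns:
        t, t_deg = ttest_score(table, fid, ttest_form)
        p, p_deg = pearson_score(table, fid)
        rows.append(
            {
                "feature": fid,
                "dice": dice_score(table, fid, by=dice_by),
                "ttest": t,
                "pearson": p,
                "degenerate_dispersion": bool(t_deg or p_deg),
            }
        )
    scores = pd.DataFrame(rows)
    for metric in ("dice", "ttest", "pearson"):
        scores[f"rank_{metric}"] = (
            scores[metric].rank(ascending=False, method="min").astype(int)
        )
    scores["rank_aggregate"] = (
        scores[["rank_dice", "rank_ttest", "rank_pearson"]]
        .mean(axis=1)
        .rank(method="first")
        .astype(int)
    )
    return scores


@dataclass
class CandidatePool:
    """Outcome of the filter stage."""

    selected: List[str]
    metric_list: List[str]
    accuracy_list: List[str]
    fallback_used: bool
    scores: pd.DataFrame = field(repr=False)

    def report(self) -> dict:
        return {
            "selected": self.selected,
            "metric_list": self.metric_list,
            "accuracy_list": self.accuracy_list,
            "fallback_used": self.fallback_used,
        }


def build_candidate_pool(
    table: LabeledFeatureTable,
    top_n: int = 40,
    svm_config: SVMConfig | None = None,
    pool_floor: int = 5,
    allow_fallback: bool = True,
    ttest_form: str = "standard",
    scores: pd.DataFrame | None = None,
) -> CandidatePool:
    """Intersect the metric-rank list with a single-feature accuracy list.

    List A holds the ``top_n`` features by mean rank across the three
    metrics; list B the ``top_n`` by single-feature cross-validated
    classifier accuracy (mean over settings).  The pool is their
    intersection; if it falls below ``pool_floor``, the union truncated to
    ``top_n`` by aggregate rank is used instead (flagged).
    """
    from .svm import cross_validate  # deferred: avoid import cycle

    svm_config = svm_config or SVMConfig()
    if scores is None:
        scores = score_table(table, ttest_form)
    if top_n > len(scores):
        raise ValueError("top_n exceeds the feature count")

    ranked = scores.sort_values("rank_aggregate")
    list_a = ranked["feature"].head(top_n).tolist()

    acc = {}
    for fid in scores["feature"]:
        per_setting = [
            cross_validate(table, [fid], svm_config, setting_id=s).mean_accuracy
            for s in table.settings
        ]
        acc[fid] = float(np.mean(per_setting))
    scores = scores.assign(
        single_feature_cv_accuracy=scores["feature"].map(acc)
    )
    list_b = (
        scores.sort_values("single_feature_cv_accuracy", ascending=False)["feature"]
        .head(top_n)
        .tolist()
    )

    inter = [f for f in list_a if f in set(list_b)]
    fallback = False
    if len(inter) < pool_floor:
        if not allow_fallback:
            raise ValueError("candidate pool empty/too small and fallback disabled")
        fallback = True
        union = [f for f in ranked["feature"] if f in set(list_a) | set(list_b)]
        inter = union[:top_n]
    scores = scores.assign(selected=scores["feature"].isin(set(inter)))
    return CandidatePool(
        selected=inter,
        metric_list=list_a,
        accuracy_list=list_b,
        fallback_used=fallback,
        scores=scores,
    )
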
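"""Filter-stage scores: hand-derived values, epsilon guards, scale
invariance, second-path oracles and candidate-pool behaviour."""

import numpy as np
import pandas as pd
import pytest

import oracles
from ultratex import (
    LabeledFeatureTable,
    SVMConfig,
    TableGenSpec,
    build_candidate_pool,
    dice_score,
    generate_feature_table,
    pearson_pairwise,
    pearson_score,
    pearson_setting,
    score_table,
    ttest_score,
    ttest_score_setting,
)
from ultratex.filters import EPSILON


def make_table(settings_values, classes=None, pair_ids=None):
    """Tiny table builder: settings_values[s] = list of F1 values."""
    rows = []
    i = 0
    for s, vals in settings_values.items():
        for j, v in enumerate(vals):
            rows.append(
                {
                    "sample_id": f"x{i}",
                    "setting_id": s,
                    "pair_id": pair_ids[s][j] if pair_ids else i,
                    "class": classes[s][j] if classes else ("IDC" if j % 2 else "BM"),
                    "F1": float(v),
                }
            )
            i += 1
    return LabeledFeatureTable(pd.DataFrame(rows))


class TestDice:
    def test_identical_setting_means_zero(self):
        t = make_table({1: [1, 3], 2: [3, 1]})
        assert dice_score(t, "F1") == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        t = make_table({1: [1, 3], 2: [5, 7]})
        assert dice_score(t, "F1") == pytest.approx(2.0, abs=1e-12)

    def test_matches_second_path(self, small_table):
        for fid in ["F1", "F5", "F9"]:
            groups = [
                small_table.setting(s)[fid].to_numpy()
                for s in small_table.settings
            ]
            assert dice_score(small_table, fid) == pytest.approx(
                oracles.dice_oracle(groups), rel=1e-12
            )


class TestTTest:
    def test_equal_class_means_zero(self):
        t = make_table(
            {1: [1.0, 2.0, 1.0, 2.0]},
            classes={1: ["BM", "BM", "IDC", "IDC"]},
        )
        assert ttest_score_setting(t, "F1", 1) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        t = make_table(
            {1: [1, 2, 3, 4, 5, 6]},
            classes={1: ["IDC"] * 3 + ["BM"] * 3},
        )
        # |1,2,3 vs 4,5,6| -> 3 / sqrt(2/3)
        assert ttest_score_setting(t, "F1", 1) == pytest.approx(
            3 / np.sqrt(2 / 3), abs=1e-12
        )

    def test_squared_numerator_form(self):
        t = make_table(
            {1: [1, 2, 3, 4, 5, 6]},
            classes={1: ["IDC"] * 3 + ["BM"] * 3},
        )
        assert ttest_score_setting(t, "F1", 1, form="squared_numerator") == pytest.approx(
            9 / np.sqrt(2 / 3), abs=1e-12
        )

    def test_aggregate_hand_example(self):
        # per-setting scores {3, 1} -> 4 / (2 * sqrt(2))
        assert oracles.aggregate_oracle([3.0, 1.0]) == pytest.approx(
            4 / (2 * np.sqrt(2)), abs=1e-12
        )

    def test_aggregate_matches_second_path(self, small_table):
        for fid in ["F1", "F7"]:
            per = [
                ttest_score_setting(small_table, fid, s)
                for s in small_table.settings
            ]
            score, flag = ttest_score(small_table, fid)
            assert score == pytest.approx(oracles.aggregate_oracle(per), rel=1e-12)
            assert not flag

    def test_degenerate_dispersion_guarded_and_flagged(self):
        # identical data in both settings -> identical per-setting scores
        vals = [1, 2, 3, 4, 5, 6]
        cls = ["IDC"] * 3 + ["BM"] * 3
        t = make_table(
            {1: vals, 2: vals},
            classes={1: cls, 2: cls},
            pair_ids={1: list(range(6)), 2: list(range(6))},
        )
        score, flag = ttest_score(t, "F1")
        assert flag and score > 1e6  # epsilon-guarded large value

    def test_permutation_lowers_planted_score(self, small_table):
        """Label permutation destroys a planted effect on average."""
        rng = np.random.default_rng(0)
        orig = ttest_score_setting(small_table, "F1", 1)
        perms = []
        df = small_table.df.copy()
        sel = df["setting_id"] == 1
        for _ in range(30):
            df.loc[sel, "class"] = rng.permutation(df.loc[sel, "class"].to_numpy())
            perms.append(
                ttest_score_setting(LabeledFeatureTable(df), "F1", 1)
            )
        assert np.mean(perms) < orig


class TestPearson:
    def test_identical_feature_perfect_correlation(self):
        t = make_table(
            {1: [1, 2, 4, 5], 2: [1, 2, 4, 5]},
            pair_ids={1: [0, 1, 2, 3], 2: [0, 1, 2, 3]},
        )
        assert pearson_pairwise(t, "F1", 1, 2) == pytest.approx(1.0)

    def test_negated_feature_anticorrelated(self):
        t = make_table(
            {1: [1, 2, 4, 5], 2: [-1, -2, -4, -5]},
            pair_ids={1: [0, 1, 2, 3], 2: [0, 1, 2, 3]},
        )
        assert pearson_pairwise(t, "F1", 1, 2) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert oracles.pearson_oracle([1, 2, 3], [1, 3, 4]) == pytest.approx(
            0.98198, abs=1e-5
        )
        t = make_table(
            {1: [1, 2, 3, 4], 2: [1, 3, 4, 4]},
            pair_ids={1: [0, 1, 2, 3], 2: [0, 1, 2, 3]},
        )
        sub = t.subset_pairs([0, 1, 2])
        # direct check against the literal formula on the matched pairs
        assert pearson_pairwise(sub, "F1", 1, 2) == pytest.approx(
            oracles.pearson_oracle([1, 2, 3], [1, 3, 4]), abs=1e-12
        )

    def test_constant_side_reported_zero(self):
        t = make_table(
            {1: [1, 2, 4, 5], 2: [3, 3, 3, 3]},
            pair_ids={1: [0, 1, 2, 3], 2: [0, 1, 2, 3]},
        )
        assert pearson_pairwise(t, "F1", 1, 2) == 0.0

    def test_setting_mean_hand_example(self):
        # |r|12 = 0.8, |r|13 = 0.6 -> 0.7 (three settings)
        assert (0.8 + 0.6) / 2 == pytest.approx(0.7)

    def test_setting_value_in_unit_interval(self, small_table):
        for fid in ["F1", "F10"]:
            for s in small_table.settings:
                assert 0.0 <= pearson_setting(small_table, fid, s) <= 1.0

    def test_aggregate_hand_example(self):
        assert oracles.aggregate_oracle([0.6, 0.7, 0.8]) == pytest.approx(
            7.0, abs=1e-9
        )

    def test_aggregate_matches_second_path(self, small_table):
        per = [pearson_setting(small_table, "F2", s) for s in small_table.settings]
        score, _ = pearson_score(small_table, "F2")
        assert score == pytest.approx(oracles.aggregate_oracle(per), rel=1e-12)


class TestInvariances:
    def test_affine_rescaling_leaves_all_metrics_unchanged(self, small_table):
        """All three scores are scale-free in a common affine rescaling."""
        df = small_table.df.copy()
        df["F1"] = 3.5 * df["F1"] - 11.0
        rescaled = LabeledFeatureTable(df)
        assert dice_score(rescaled, "F1") == pytest.approx(
            dice_score(small_table, "F1"), rel=1e-9
        )
        assert ttest_score(rescaled, "F1")[0] == pytest.approx(
            ttest_score(small_table, "F1")[0], rel=1e-9
        )
        assert pearson_score(rescaled, "F1")[0] == pytest.approx(
            pearson_score(small_table, "F1")[0], rel=1e-9
        )

    def test_rankings_permutation_equivariant(self, small_table):
        """Relabeling features permutes the ranking accordingly."""
        scores = score_table(small_table)
        df = small_table.df.rename(columns={"F1": "F12", "F12": "F1"})
        swapped_scores = score_table(LabeledFeatureTable(df))
        orig = scores.set_index("feature")["dice"]
        swap = swapped_scores.set_index("feature")["dice"]
        assert swap["F12"] == pytest.approx(orig["F1"])
        assert swap["F1"] == pytest.approx(orig["F12"])

    def test_planted_features_outrank_noise_on_class_sensitive_metrics(self):
        spec = TableGenSpec(
            n_settings=4,
            n_per_class_per_setting=100,
            n_features=20,
            universal_informative=("F1", "F2", "F3"),
            effect_size=2.0,
            seed=11,
        )
        t = generate_feature_table(spec)
        scores = score_table(t).set_index("feature")
        planted = {"F1", "F2", "F3"}
        noise = [f for f in t.feature_columns if f not in planted]
        for metric in ("dice", "ttest", "pearson"):
            worst_planted = min(scores.loc[sorted(planted), metric])
            best_noise = max(scores.loc[noise, metric])
            assert worst_planted > best_noise, metric


class TestCandidatePool:
    def test_planted_features_enter_pool(self):
        spec = TableGenSpec(
            n_settings=4,
            n_per_class_per_setting=60,
            n_features=30,
            universal_informative=("F1", "F2", "F3", "F4", "F5"),
            effect_size=2.0,
            seed=3,
        )
        t = generate_feature_table(spec)
        pool = build_candidate_pool(t, top_n=10, svm_config=SVMConfig(folds=3))
        assert {"F1", "F2", "F3", "F4", "F5"} <= set(pool.selected)

    def test_full_overlap_gives_top_n(self, small_table):
        pool = build_candidate_pool(
            small_table, top_n=len(small_table.feature_columns),
            svm_config=SVMConfig(folds=2),
        )
        assert len(pool.selected) == len(small_table.feature_columns)
        assert not pool.fallback_used

    def test_fallback_truncated_union_flagged(self, small_table):
        pool = build_candidate_pool(
            small_table, top_n=3, svm_config=SVMConfig(folds=2),
            pool_floor=4,  # intersection of size <= 3 must trigger fallback
        )
        assert pool.fallback_used
        assert 1 <= len(pool.selected) <= 3

    def test_top_n_exceeding_features_rejected(self, small_table):
        with pytest.raises(ValueError):
            build_candidate_pool(small_table, top_n=999)
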
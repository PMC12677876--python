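"""Labels, feature assembly, grouped splits, oversampling, thresholding,
evaluation and permutation importance for the severity classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from actimood import (
    ClassifierConfig,
    SeverityModel,
    assemble_features,
    evaluate,
    grouped_splits,
    make_labels,
    oversample_minority,
    sweep_threshold,
)
from actimood.errors import IntegrityError, SplitError


def _met_daily(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "mood_pos_max", "mood_neg_max"]
    )


class TestMakeLabels:
    def test_severe_boundary_at_seven(self):
        md = _met_daily([
            ("p", "2022-01-01", 7, 0),
            ("p", "2022-01-02", 6, 6),
            ("p", "2022-01-03", 0, 7),
        ])
        lab = make_labels(md)
        assert lab["severe_day"].tolist() == [1.0, 0.0, 1.0]

    def test_tomorrow_is_shifted_same_patient(self):
        md = _met_daily([
            ("p", "2022-01-01", 7, 0),
            ("p", "2022-01-02", 0, 0),
            ("q", "2022-01-02", 8, 0),
        ])
        lab = make_labels(md).set_index(["patient_id", "date"])
        assert lab.loc[("p", "2022-01-01"), "severe_tomorrow"] == 0.0
        # last day of p, and q's single day: missing
        assert np.isnan(lab.loc[("p", "2022-01-02"), "severe_tomorrow"])
        assert np.isnan(lab.loc[("q", "2022-01-02"), "severe_tomorrow"])

    def test_gap_yields_missing_tomorrow(self):
        md = _met_daily([
            ("p", "2022-01-01", 0, 0),
            ("p", "2022-01-03", 9, 0),  # gap: Jan 2 missing
        ])
        lab = make_labels(md)
        assert np.isnan(lab["severe_tomorrow"].iloc[0])

    def test_shift_identity_on_generated_cohort(self, small_tables):
        _, met_daily, _ = small_tables
        lab = make_labels(met_daily).sort_values(["patient_id", "date"])
        dates = pd.to_datetime(lab["date"])
        adjacent = (lab["patient_id"].shift(-1) == lab["patient_id"]) & (
            (dates.shift(-1) - dates).dt.days == 1
        )
        nxt = lab["severe_day"].shift(-1)
        mask = adjacent & lab["severe_tomorrow"].notna() & nxt.notna()
        assert (lab.loc[mask, "severe_tomorrow"] == nxt[mask]).all()


class TestAssembleFeatures:
    def test_mood_column_smuggled_raises(self, small_tables):
        feats, met_daily, patients = small_tables
        poisoned = feats.assign(mood_mean_leak=1.0)
        with pytest.raises(IntegrityError):
            assemble_features(poisoned, met_daily, patients)

    def test_duplicate_keys_raise(self, small_tables):
        feats, met_daily, patients = small_tables
        dup = pd.concat([feats, feats.iloc[:1]], ignore_index=True)
        with pytest.raises(IntegrityError):
            assemble_features(dup, met_daily, patients)

    def test_no_mood_columns_and_indicators_present(self, small_tables):
        feats, met_daily, patients = small_tables
        X = assemble_features(feats, met_daily, patients)
        assert not any("mood" in c.lower() for c in X.columns)
        assert any(c.startswith("group_") for c in X.columns)
        assert any(c.startswith("gender_") for c in X.columns)
        assert "energy_range" in X.columns and "max1" in X.columns


class TestGroupedSplits:
    def test_ten_patients_five_folds(self):
        groups = np.repeat([f"p{i}" for i in range(10)], 3)
        folds = grouped_splits(groups, 5)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(30))  # exact partition
        for tr, te in folds:
            assert set(groups[tr]) & set(groups[te]) == set()
            assert len(set(groups[te])) == 2

    def test_too_few_patients(self):
        with pytest.raises(SplitError):
            grouped_splits(np.array(["a", "a", "b"]), 5)


class TestOversampleMinority:
    def test_balanced_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        X2, y2 = oversample_minority(X, y, 5, rng)
        assert X2.shape == X.shape and (y2 == y).all()

    def test_counting_100_20(self, rng):
        X = rng.normal(size=(120, 4))
        y = np.array([0] * 100 + [1] * 20)
        X2, y2 = oversample_minority(X, y, 5, rng)
        assert (y2 == 0).sum() == 100 and (y2 == 1).sum() == 100

    def test_identical_minority_rows_interpolate_to_themselves(self, rng):
        X = np.vstack([rng.normal(size=(8, 3)), np.ones((2, 3))])
        y = np.array([0] * 8 + [1] * 2)
        X2, y2 = oversample_minority(X, y, 5, rng)
        synthetic = X2[len(X):]
        assert np.allclose(synthetic, 1.0)

    def test_singleton_minority_duplicates(self, rng):
        X = np.vstack([rng.normal(size=(5, 3)), [[9.0, 9.0, 9.0]]])
        y = np.array([0] * 5 + [1])
        X2, y2 = oversample_minority(X, y, 5, rng)
        assert (y2 == 1).sum() == 5
        assert np.allclose(X2[6:], [9.0, 9.0, 9.0])

    def test_synthetic_rows_are_convex_combinations(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array([0] * 25 + [1] * 5)
        X2, _ = oversample_minority(X, y, 3, rng)
        minority = X[y == 1]
        for row in X2[len(X):]:
            # each synthetic point lies within the minority bounding box
            assert (row >= minority.min(0) - 1e-9).all()
            assert (row <= minority.max(0) + 1e-9).all()


class TestThresholdSweep:
    def test_grid_argmax_by_hand(self):
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        y = np.array([0, 0, 1, 1])
        # any threshold in (0.4, 0.6] is perfect; grid point 0.45..0.6 ->
        # ties broken toward 0.5
        t = sweep_threshold(scores, y, (0.05, 0.95, 0.05))
        assert t == 0.5

    def test_tie_toward_half_then_lower(self):
        scores = np.array([0.2, 0.8])
        y = np.array([0, 1])
        t = sweep_threshold(scores, y, (0.05, 0.95, 0.05))
        assert t == 0.5  # all thresholds in (0.2,0.8] perfect; 0.5 closest

    def test_separable_reaches_perfect_accuracy(self):
        scores = np.array([0.05, 0.1, 0.9, 0.95])
        y = np.array([0, 0, 1, 1])
        t = sweep_threshold(scores, y)
        assert ((scores >= t).astype(int) == y).all()


class TestEvaluate:
    def test_scores_equal_labels(self):
        y = np.array([0, 1, 0, 1, 1])
        m = evaluate(y.astype(float), 0.5, y)
        assert m["roc_auc"] == 1.0 and m["f1"] == 1.0
        assert m["tn"] + m["fp"] + m["fn"] + m["tp"] == len(y)

    def test_auc_equals_rank_statistic(self):
        scores = np.array([0.1, 0.3, 0.35, 0.6, 0.7, 0.95])
        y = np.array([0, 0, 1, 0, 1, 1])
        m = evaluate(scores, 0.5, y)
        u = stats.mannwhitneyu(
            scores[y == 1], scores[y == 0], alternative="two-sided"
        ).statistic
        assert m["roc_auc"] == pytest.approx(u / (3 * 3))

    def test_single_class_fold_missing_auc(self):
        y = np.ones(4, dtype=int)
        m = evaluate(np.array([0.6, 0.7, 0.8, 0.9]), 0.5, y)
        assert np.isnan(m["roc_auc"]) and np.isnan(m["pr_auc"])
        assert m["accuracy"] == 1.0


def _synthetic_learnable(n_patients=20, days=8, seed=0):
    """Feature/label tables where one feature fully determines the label."""
    rng = np.random.default_rng(seed)
    rows_f, rows_m = [], []
    for p in range(n_patients):
        pid = f"p{p:02d}"
        for d in range(days):
            date = f"2022-01-{d + 1:02d}"
            driver = rng.normal()
            severe = driver > 0.3
            feat = {
                "patient_id": pid, "date": date, "day_usable": True,
                "features_ok": True,
                "total_ac": driver * 10.0,  # label-defining feature
                "std_ac": rng.normal(), "max_ac": rng.normal(),
            }
            rows_f.append(feat)
            rows_m.append({
                "patient_id": pid, "date": date,
                "mood_pos_max": 9.0 if severe else 1.0, "mood_neg_max": 0.0,
                "energy_pos_max": rng.normal(), "energy_neg_max": rng.normal(),
                "energy_min": rng.normal(), "energy_max": rng.normal(),
                "energy_mean": rng.normal(), "energy_range": abs(rng.normal()),
                "energy_pos_min": 0.0, "energy_neg_min": 0.0,
            })
    patients = pd.DataFrame({
        "patient_id": [f"p{p:02d}" for p in range(n_patients)],
        "group": ["A", "B"] * (n_patients // 2),
        "age_months": 180, "gender": ["F", "M"] * (n_patients // 2),
    })
    return pd.DataFrame(rows_f), pd.DataFrame(rows_m), patients


class TestSeverityModelEndToEnd:
    def test_separable_fixture_learned_and_leak_free(self):
        feats, met_daily, patients = _synthetic_learnable()
        X = assemble_features(feats, met_daily, patients)
        labels = make_labels(met_daily)
        res = SeverityModel(
            X, labels, "severe_day", "logistic_regression",
            ClassifierConfig(seed=0),
        ).fit()
        res.assert_leak_free()
        assert res.aggregate["roc_auc"] > 0.95

    def test_label_defining_feature_ranks_first(self):
        feats, met_daily, patients = _synthetic_learnable()
        X = assemble_features(feats, met_daily, patients)
        labels = make_labels(met_daily)
        res = SeverityModel(
            X, labels, "severe_day", "logistic_regression",
            ClassifierConfig(seed=0),
        ).fit()
        imp = res.permutation_importance(n_repeats=3)
        assert imp["feature"].iloc[0] == "total_ac"
        # pure-noise features carry ~zero importance
        noise_imp = imp.set_index("feature")["importance"]["std_ac"]
        assert abs(noise_imp) < 0.05

    def test_permutation_repeats_must_be_positive(self):
        feats, met_daily, patients = _synthetic_learnable()
        X = assemble_features(feats, met_daily, patients)
        res = SeverityModel(
            X, make_labels(met_daily), "severe_day", "logistic_regression",
            ClassifierConfig(seed=0),
        ).fit()
        with pytest.raises(ValueError):
            res.permutation_importance(n_repeats=0)

    def test_fit_is_deterministic(self):
        feats, met_daily, patients = _synthetic_learnable()
        X = assemble_features(feats, met_daily, patients)
        labels = make_labels(met_daily)

        def run():
            return SeverityModel(
                X, labels, "severe_day", "logistic_regression",
                ClassifierConfig(seed=3),
            ).fit().fold_metrics

        pd.testing.assert_frame_equal(run(), run())

    def test_tomorrow_uses_fewer_rows(self, small_tables):
        feats, met_daily, _ = small_tables
        lab = make_labels(met_daily)
        assert lab["severe_tomorrow"].notna().sum() < lab["severe_day"].notna().sum()
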
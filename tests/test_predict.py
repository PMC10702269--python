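"""Classifier evaluation, analytic baselines, sweeps and associations."""

import numpy as np
import pandas as pd
import pytest

from seizclust.predict import (
    BaselinePerformance,
    CVConfig,
    _fit_fold,
    baseline_performance,
    characteristic_association,
    run_task,
    sample_size_sweep,
)


def gaussian_features(n_pos, n_neg, shift=0.0, seed=0, pid="p0"):
    """Feature frame with a controllable class separation."""
    rng = np.random.default_rng(seed)
    rows = []
    for y in ([1] * n_pos) + ([0] * n_neg):
        row = {"patient_id": pid,
               "category": "cluster_non_last" if y else "isolated",
               "is_cluster_first": bool(y)}
        for i in range(10):
            row[f"ga_ren_f{i}_x"] = rng.standard_normal() + shift * y
        rows.append(row)
    rng.shuffle(rows)
    return pd.DataFrame(rows)


class TestBaselines:
    # printed per-patient class sizes and table values (percent, 1 decimal):
    # (n_neg, n_pos) -> precision, baseline-1 F1, baseline-2 F1
    NEXT_SEIZURE_ROWS = [
        (73, 107, 59.4, 54.3, 74.6),
        (28, 648, 95.9, 65.7, 97.9),
        (83, 646, 88.6, 63.9, 94.0),
        (132, 148, 52.9, 51.4, 69.2),
        (100, 793, 88.8, 64.0, 94.1),
        (28, 10, 26.3, 34.5, 41.7),
        (228, 540, 70.3, 58.4, 82.6),
        (83, 18, 17.8, 26.3, 30.3),
    ]
    CLUSTER_ONSET_ROWS = [
        (31, 42, 57.5, 53.5, 73.0),
        (13, 70, 84.3, 62.8, 91.5),
        (65, 67, 50.8, 50.4, 67.3),
        (19, 81, 81.0, 61.8, 89.5),
        (101, 127, 55.7, 52.7, 71.5),
    ]

    @pytest.mark.parametrize(
        "n_neg,n_pos,precision,f1_b1,f1_b2",
        NEXT_SEIZURE_ROWS + CLUSTER_ONSET_ROWS,
    )
    def test_closed_forms_reproduce_published_rows(
        self, n_neg, n_pos, precision, f1_b1, f1_b2
    ):
        row = BaselinePerformance.from_counts(n_neg, n_pos, q=0.5).as_percent_row()
        assert row["precision_b1"] == precision
        assert row["precision_b2"] == precision
        assert row["recall_b1"] == 50.0
        assert row["recall_b2"] == 100.0
        assert row["f1_b1"] == f1_b1
        assert row["f1_b2"] == f1_b2
        assert row["auc_b1"] == 50.0

    def test_prevalence_limit(self):
        assert BaselinePerformance(r=0.999).f1_b2 > 0.999

    def test_degenerate_prevalence_rejected(self):
        for r in (0.0, 1.0):
            with pytest.raises(ValueError):
                baseline_performance(r)

    def test_formulas_match_simulated_predictions(self):
        rng = np.random.default_rng(1)
        n = 200_000
        for r, q in [(0.3, 0.5), (0.85, 0.5), (0.6, 0.2), (0.1, 0.9)]:
            y = rng.random(n) < r
            pred1 = rng.random(n) < q  # baseline 1: chance at rate q
            tp = np.sum(y & pred1)
            prec1 = tp / pred1.sum()
            rec1 = tp / y.sum()
            f1_1 = 2 * prec1 * rec1 / (prec1 + rec1)
            bp = baseline_performance(r, q)
            assert prec1 == pytest.approx(bp.precision_b1, abs=0.01)
            assert rec1 == pytest.approx(bp.recall_b1, abs=0.01)
            assert f1_1 == pytest.approx(bp.f1_b1, abs=0.01)
            # baseline 2: always positive
            assert y.mean() == pytest.approx(bp.precision_b2, abs=0.01)
            assert 2 * y.mean() / (y.mean() + 1) == pytest.approx(bp.f1_b2, abs=0.01)


class TestRunTask:
    def test_separable_classes_perfect_metrics(self):
        feats = gaussian_features(30, 30, shift=20.0, seed=2)
        cfg = CVConfig(models=("knn",), seed=0)
        report = run_task(feats, "next_seizure", cfg)
        agg = report.aggregate()
        assert agg.auc_mean[0] == pytest.approx(1.0)
        assert agg.f1_mean[0] == pytest.approx(1.0)

    def test_reproducible_given_seed(self):
        feats = gaussian_features(40, 25, shift=0.5, seed=3)
        cfg = CVConfig(models=("logistic_regression",), seed=5)
        r1 = run_task(feats, "next_seizure", cfg)
        r2 = run_task(feats, "next_seizure", cfg)
        pd.testing.assert_frame_equal(r1.folds, r2.folds)

    def test_class_too_small_raises(self):
        feats = gaussian_features(3, 40)
        with pytest.raises(ValueError, match="class counts"):
            run_task(feats, "next_seizure", CVConfig(models=("knn",)))

    def test_cluster_onset_uses_first_vs_isolated_only(self):
        feats = gaussian_features(30, 30, shift=20.0, seed=4)
        # add rows that must be excluded from the task
        extra = gaussian_features(10, 0, seed=5)
        extra["category"] = "cluster_last"
        extra["is_cluster_first"] = False
        cfg = CVConfig(models=("decision_tree",), seed=1)
        report = run_task(pd.concat([feats, extra], ignore_index=True),
                          "cluster_onset", cfg)
        n_used = report.baselines.r  # prevalence over included rows only
        assert n_used == pytest.approx(0.5)

    def test_no_leakage_from_test_fold_into_selection(self):
        # canary: a feature that is noise on the training side but equals
        # the label on the test side; without leakage the fitted model
        # cannot exploit it, so test AUC stays near chance
        rng = np.random.default_rng(6)
        n_tr, n_te = 120, 60
        y_tr = np.array([0, 1] * (n_tr // 2))
        y_te = np.array([0, 1] * (n_te // 2))
        X_tr = rng.standard_normal((n_tr, 5))
        X_te = rng.standard_normal((n_te, 5))
        X_tr[:, 0] = rng.standard_normal(n_tr)  # canary: noise in train
        X_te[:, 0] = y_te  # canary: label in test
        est = _fit_fold("logistic_regression", {"model__C": [0.1, 1.0, 10.0]},
                        X_tr, y_tr, inner_folds=5, seed=0)
        from sklearn.metrics import roc_auc_score
        auc = roc_auc_score(y_te, est.predict_proba(X_te)[:, 1])
        assert auc < 0.75

    def test_balanced_weighting_makes_trivial_classifier_indifferent(self):
        # one constant feature, 9:1 imbalance: with inverse-frequency class
        # weights the fitted model has no reason to prefer either class
        feats = gaussian_features(90, 10, shift=0.0)
        for c in feats.columns:
            if c.startswith("ga_ren_"):
                feats[c] = 1.0
        from seizclust.predict import _make_estimator
        est = _make_estimator("logistic_regression", 0)
        X = feats[[c for c in feats.columns if c.startswith("ga_ren_")]].to_numpy()
        y = (feats.category == "cluster_non_last").astype(int).to_numpy()
        est.fit(X, y)
        proba = est.predict_proba(X)[:, 1]
        assert np.abs(proba - 0.5).max() < 0.05


class TestSampleSizeSweep:
    def test_fraction_schedule_sizes_and_zero_sd_at_full(self):
        feats = gaussian_features(80, 60, shift=1.0, seed=7)
        df = sample_size_sweep(feats, "next_seizure", CVConfig(seed=0),
                               schedule="fractions")
        assert df.size_label.tolist() == [20, 40, 60, 80, 100]
        n_pool = int(round(0.8 * 140))
        assert df.n_train.iloc[-1] == n_pool
        assert df.auc_sd.iloc[-1] == 0.0

    def test_powers_schedule_caps_at_pool(self):
        feats = gaussian_features(50, 40, shift=1.0, seed=8)
        df = sample_size_sweep(feats, "next_seizure", CVConfig(seed=0),
                               schedule="powers")
        assert df.size_label.tolist() == [16, 32, 64, 128, 256, 512]
        assert df.n_train.iloc[0] == 16
        pool = int(round(0.8 * 90))
        assert (df.n_train <= pool).all()

    def test_strong_effect_auc_increases_with_size(self):
        feats = gaussian_features(150, 100, shift=0.8, seed=9)
        df = sample_size_sweep(feats, "next_seizure", CVConfig(seed=1),
                               schedule="powers")
        assert df.auc_mean.iloc[-1] > df.auc_mean.iloc[0]


class TestCharacteristicAssociation:
    def make_table(self):
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(8)],
            "sex": ["M", "F"] * 4,
            "age": [26, 44, 52, 48, 51, 50, 43, 50],
        })

    def test_identical_aucs_p_one(self):
        aucs = {f"p{i}": 0.7 for i in range(8)}
        df = characteristic_association(aucs, self.make_table(),
                                        categorical=["sex"])
        assert df.p.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_auc_ordered_by_age_perfect_rank_correlation(self):
        table = self.make_table()
        table["age"] = np.arange(8)
        aucs = {f"p{i}": 0.5 + 0.05 * i for i in range(8)}
        df = characteristic_association(aucs, table, continuous=["age"])
        assert abs(df.statistic.iloc[0]) == pytest.approx(1.0)

    def test_degenerate_grouping_untestable(self):
        aucs = {f"p{i}": 0.6 for i in range(8)}
        table = self.make_table()
        table["sex"] = "M"
        df = characteristic_association(aucs, table, categorical=["sex"])
        assert not df.testable.iloc[0]

    def test_null_characteristics_give_uniformish_p(self):
        rng = np.random.default_rng(10)
        ps = []
        table = self.make_table()
        for _ in range(200):
            aucs = {f"p{i}": rng.random() for i in range(8)}
            df = characteristic_association(aucs, table, categorical=["sex"])
            ps.append(df.p.iloc[0])
        # calibrated test: small p-values occur at roughly their nominal rate
        assert 0.02 < np.mean(np.array(ps) < 0.3) < 0.6
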
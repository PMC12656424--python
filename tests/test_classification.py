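"""Metrics, balanced fold construction, and the two SVM regimes."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_feature_table
from swallowsense.classification import (FoldAssignment, compute_metrics,
                                         fit_plane_svm, make_fold_assignments,
                                         run_cv)
from swallowsense.errors import ConfigError, ValidationError
from swallowsense.io import load_clinical
from swallowsense.reduction import mrmr_select


class TestMetrics:
    def test_worked_confusion_example(self):
        m = compute_metrics({"tp": 9, "fn": 1, "fp": 2, "tn": 8})
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(9 / 11)
        assert m["recall"] == pytest.approx(0.9)
        assert m["f1"] == pytest.approx(2 * (9 / 11) * 0.9 / (9 / 11 + 0.9))

    def test_perfect_diagonal_all_ones(self):
        m = compute_metrics({"tp": 10, "fn": 0, "fp": 0, "tn": 10})
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall",
                                         "f1", "kappa"))

    def test_uniform_counts_chance_kappa(self):
        m = compute_metrics({"tp": 5, "fn": 5, "fp": 5, "tn": 5})
        assert m["accuracy"] == 0.5
        assert m["kappa"] == 0.0

    def test_single_class_predictions_zero_kappa(self):
        m = compute_metrics({"tp": 15, "fn": 0, "fp": 7, "tn": 0})
        assert m["kappa"] == 0.0

    def test_undefined_metrics_are_none_not_zero(self):
        m = compute_metrics({"tp": 0, "fn": 0, "fp": 0, "tn": 10})
        assert m["recall"] is None
        assert m["precision"] is None

    def test_metrics_match_independent_tally(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(["PD", "HC"], 200)
        y_pred = rng.choice(["PD", "HC"], 200)
        from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score
        from swallowsense.classification import _tally
        m = compute_metrics(_tally(y_true, y_pred))
        assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
        assert m["f1"] == pytest.approx(
            f1_score(y_true, y_pred, pos_label="PD"))
        assert m["kappa"] == pytest.approx(cohen_kappa_score(y_true, y_pred))


class TestFoldAssignments:
    def test_study_cohort_arithmetic(self):
        clinical = load_clinical()     # 15 PD + 7 HC
        fas = make_fold_assignments(clinical, n_seeds=3, base_seed=0)
        for fa in fas:
            assert len(fa.folds) == 3
            for fold in fa.folds:
                ids = sorted(fold)
                assert len(ids) == 4
                assert sum(1 for s in ids if s.startswith("HC")) == 2
            assert len(fa.leftover) == 10     # 9 PD + 1 HC train-only
            hc_left = sum(1 for s in fa.leftover if s.startswith("HC"))
            assert hc_left == 1

    def test_assignments_deterministic_per_base_seed(self):
        clinical = load_clinical()
        a = make_fold_assignments(clinical, n_seeds=5, base_seed=42)
        b = make_fold_assignments(clinical, n_seeds=5, base_seed=42)
        assert a == b

    def test_500_seeds_are_diverse(self):
        clinical = load_clinical()
        fas = make_fold_assignments(clinical, n_seeds=500, base_seed=0)
        distinct = {fa.folds for fa in fas}
        assert len(distinct) >= 2

    def test_tiny_class_rejected(self):
        clinical = pd.DataFrame({"id": ["a", "b", "c"],
                                 "group": ["PD", "PD", "HC"]})
        with pytest.raises(ConfigError):
            make_fold_assignments(clinical, n_seeds=1)


class TestPlaneSVM:
    def test_separable_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((45, 2)) + [6.0, 6.0]
        b = rng.standard_normal((21, 2)) - [6.0, 6.0]
        scores = np.vstack([a, b])
        labels = np.array(["PD"] * 45 + ["HC"] * 21)
        res = fit_plane_svm(scores, labels)
        assert res.training_metrics["accuracy"] == 1.0

    def test_inverse_class_frequency_weights(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal((66, 2))
        labels = np.array(["PD"] * 45 + ["HC"] * 21)
        res = fit_plane_svm(scores, labels)
        cw = dict(zip(res.model.classes_, res.model.class_weight_))
        assert cw["HC"] / cw["PD"] == pytest.approx(45 / 21)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            fit_plane_svm(np.zeros((5, 2)), ["PD"] * 5)


def _assignments_for(df, n_seeds, base_seed=0):
    clinical = df[["subject_id", "group"]].drop_duplicates() \
        .rename(columns={"subject_id": "id"})
    return make_fold_assignments(clinical, n_seeds=n_seeds, base_seed=base_seed)


class TestRunCV:
    def test_splits_partition_subjects_and_count_test_trials(self):
        rng = np.random.default_rng(3)
        df = make_feature_table(rng, n_pd=4, n_hc=4, trials=2, n_features=6)
        fa = FoldAssignment(seed=0, folds=(frozenset({"PD00", "PD01",
                                                      "HC00", "HC01"}),),
                            leftover=frozenset(set(df["subject_id"])
                                               - {"PD00", "PD01", "HC00", "HC01"}))
        report = run_cv(df, None, [fa], components=(1, 2))
        cm = report.per_seed[0].confusion
        assert cm["tp"] + cm["fn"] == 4           # 2 PD test subjects x 2 trials
        assert sum(cm.values()) == 8              # exactly the fold's trials
        for fold in fa.folds:
            assert fold.isdisjoint(fa.leftover)

    def test_identical_assignments_zero_seed_spread(self):
        rng = np.random.default_rng(4)
        df = make_feature_table(rng, n_pd=6, n_hc=6, trials=3, n_features=10,
                                informative=(0, 1), shift=2.0)
        fas = _assignments_for(df, n_seeds=1)
        report = run_cv(df, None, fas * 5, components=(1, 2))
        assert report.aggregate["accuracy"]["sd"] == 0.0

    def test_null_features_give_chance_accuracy(self):
        rng = np.random.default_rng(5)
        df = make_feature_table(rng, n_pd=8, n_hc=8, trials=3, n_features=10)
        fas = _assignments_for(df, n_seeds=40)
        report = run_cv(df, None, fas, components=(1, 2))
        assert 0.3 <= report.aggregate["accuracy"]["mean"] <= 0.7

    def test_accuracy_monotone_in_effect_size(self):
        accs = []
        for shift in (0.0, 1.0, 3.0):
            rng = np.random.default_rng(6)
            df = make_feature_table(rng, n_pd=8, n_hc=8, trials=3,
                                    n_features=10, informative=(0, 1, 2),
                                    shift=shift)
            fas = _assignments_for(df, n_seeds=20)
            accs.append(run_cv(df, None, fas,
                               components=(1, 2)).aggregate["accuracy"]["mean"])
        assert accs[2] >= accs[1] - 0.05 >= accs[0] - 0.10
        assert accs[2] >= 0.9


class TestEndToEndCohorts:
    def test_null_cohort_cv_is_calibrated(self, null_cohort):
        """No group effect -> mean CV accuracy near chance over 100 fold seeds."""
        clinical, features, _ = null_cohort
        sel = mrmr_select(features, features["group"], k=15)
        fas = make_fold_assignments(clinical, n_seeds=100, base_seed=0)
        report = run_cv(features, sel, fas)
        assert abs(report.aggregate["accuracy"]["mean"] - 0.5) <= 0.10

    def test_separated_cohort_cv_has_power(self, separated_cohort):
        """Strong planted effect -> mean CV accuracy >= 90% over 50 fold seeds."""
        clinical, features, _ = separated_cohort
        sel = mrmr_select(features, features["group"], k=15)
        fas = make_fold_assignments(clinical, n_seeds=50, base_seed=0)
        report = run_cv(features, sel, fas)
        assert report.aggregate["accuracy"]["mean"] >= 0.90

    def test_separated_cohort_silhouette_improves_after_selection(self,
                                                                  separated_cohort):
        from sklearn.metrics import silhouette_score
        from swallowsense.reduction import fit_pca, project, standardize_features
        _, features, _ = separated_cohort
        cols = [c for c in features.columns
                if c not in ("subject_id", "task", "trial", "group")]
        labels = features["group"].to_numpy()
        std, _ = standardize_features(features, cols)
        s_all = silhouette_score(project(fit_pca(std, cols, 3), std), labels)
        sel = mrmr_select(std, features["group"], k=15, feature_cols=cols)
        sub = list(sel.selected)
        std2, _ = standardize_features(features, sub)
        s_sel = silhouette_score(project(fit_pca(std2, sub, 3), std2), labels)
        assert s_sel > s_all
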
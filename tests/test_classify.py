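import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsvote.classify import (
    CVConfig,
    ModelSpec,
    SingleClassError,
    confusion_metrics,
    cross_validate,
    default_model_specs,
    fit_final,
    make_folds,
    rank_auc,
)
from omicsvote.io import PEPTIDE, FeatureTable
from omicsvote.simulate import SyntheticSpec, generate_cohort


def toy_table(n=40, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = y + rng.normal(0, 0.1 if separable else 10.0, n)
    df = pd.DataFrame({"f1": x, "f2": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)])
    return FeatureTable(
        data=df, labels=pd.Series(y, index=df.index),
        feature_kinds={c: PEPTIDE for c in df.columns},
    )


class TestMakeFolds:
    def test_cohort_of_143_into_10(self):
        cohort = generate_cohort(SyntheticSpec(n_pca=69, n_bph=74, n_peptides=3, seed=1))
        folds = make_folds(cohort.table, CVConfig(k=10, seed=0))
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {14, 15}
        assert sorted(np.concatenate(folds).tolist()) == list(range(143))

    def test_leave_one_out_unstratified(self):
        t = toy_table(n=8)
        folds = make_folds(t, CVConfig(k=8, stratified=False, seed=0))
        assert all(len(f) == 1 for f in folds)

    def test_same_seed_identical(self):
        t = toy_table(n=30)
        a = make_folds(t, CVConfig(k=5, seed=3))
        b = make_folds(t, CVConfig(k=5, seed=3))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_stratified_fold_balance(self):
        cohort = generate_cohort(SyntheticSpec(n_pca=67, n_bph=54, n_peptides=3, seed=1))
        y = cohort.table.y()
        folds = make_folds(cohort.table, CVConfig(k=10, seed=0))
        pos = [int(y[f].sum()) for f in folds]
        assert max(pos) - min(pos) <= 1

    def test_small_class_errors(self):
        t = toy_table(n=10)
        t.labels.iloc[:] = [1] * 9 + [0]
        with pytest.raises(ValueError, match="smaller k"):
            make_folds(t, CVConfig(k=5, seed=0))


class TestConfusionMetrics:
    def test_validation_report_worked_example(self, table2_preds):
        m = confusion_metrics(table2_preds.y_true, table2_preds.hard_labels)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (5, 1, 5, 1)
        assert m["accuracy"] == pytest.approx(10 / 12)
        assert m["sensitivity"] == pytest.approx(5 / 6)
        assert m["specificity"] == pytest.approx(5 / 6)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1])
        m = confusion_metrics(y, y, y.astype(float))
        assert all(m[k] == 1.0 for k in ("accuracy", "f1", "sensitivity", "specificity", "auc"))

    def test_constant_score_auc_half(self):
        y = np.array([0, 1, 0, 1, 1])
        assert rank_auc(y, np.full(5, 0.7)) == pytest.approx(0.5)

    def test_single_class_auc_undefined(self):
        with pytest.raises(SingleClassError):
            rank_auc(np.ones(4, dtype=int), np.random.rand(4))

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        y = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        m = confusion_metrics(y, p)
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        assert m["tp"] == tp and m["tn"] == tn
        assert m["accuracy"] * n == pytest.approx(tp + tn)

    @pytest.mark.parametrize("seed", range(5))
    def test_rank_auc_equals_trapezoidal_roc_area(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 50))
        y = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
        s = np.round(rng.random(n), 2)  # coarse grid forces ties
        auc = rank_auc(y, s)
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(y, s)
        assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_auc_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(4, 20))
        y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        # coarse grid: distinct scores stay distinct under the transforms
        # (strict monotonicity is only guaranteed in exact arithmetic)
        s = np.round(np.array(data.draw(st.lists(
            st.floats(0.01, 0.99, allow_nan=False), min_size=n, max_size=n))), 3)
        base = rank_auc(y, s)
        for f in (lambda v: 3 * v + 1, np.exp, lambda v: v**3):
            assert rank_auc(y, f(s)) == pytest.approx(base, abs=1e-12)


class TestCrossValidate:
    def test_label_copy_near_perfect(self):
        t = toy_table(n=40, separable=True)
        specs = [ModelSpec(kind="LR"), ModelSpec(kind="KNN")]
        report = cross_validate(t, specs, CVConfig(k=5, seed=0))
        assert report.mean_metric("LR", "accuracy") >= 0.95
        assert report.mean_metric("KNN", "accuracy") >= 0.95

    def test_identical_specs_identical_rows(self):
        t = toy_table(n=40)
        specs = [ModelSpec(kind="DT", seed=5), ModelSpec(kind="DT", seed=5)]
        report = cross_validate(t, specs, CVConfig(k=4, seed=0))
        assert report.model_kinds == ["DT", "DT#2"]
        assert report.fold_metrics["DT"] == report.fold_metrics["DT#2"]

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_validate(toy_table(), [], CVConfig(k=4))

    def test_degenerate_fold_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        y = np.array([1] + [0] * 7)
        df = pd.DataFrame({"f": rng.normal(size=8)}, index=[f"s{i}" for i in range(8)])
        t = FeatureTable(data=df, labels=pd.Series(y, index=df.index),
                         feature_kinds={"f": PEPTIDE})
        with pytest.warns(UserWarning, match="skipped"):
            report = cross_validate(t, [ModelSpec(kind="DT")],
                                    CVConfig(k=8, stratified=False, seed=1))
        assert report.n_folds_completed["DT"] < 8

    def test_best_model_has_max_auc(self):
        cohort = generate_cohort(SyntheticSpec(n_pca=30, n_bph=30, n_peptides=8,
                                               clinical_params={}, seed=2))
        specs = [ModelSpec(kind=k, hyperparams={"n_estimators": 50} if k == "RF" else {})
                 for k in ("LR", "DT", "RF")]
        report = cross_validate(cohort.table, specs, CVConfig(k=5, seed=0))
        best_auc = report.mean_metric(report.best_model, "auc")
        assert all(report.mean_metric(k, "auc") <= best_auc + 1e-12 for k in report.model_kinds)
        assert all(0 <= report.mean_metric(k, m) <= 1
                   for k in report.model_kinds for m in ("auc", "accuracy", "f1"))


class TestFitFinal:
    def test_resubstitution_on_separable_toy(self):
        t = toy_table(n=30, separable=True)
        model = fit_final(t, ModelSpec(kind="LR"))
        assert (model.predict(t) == t.y()).all()

    def test_serialization_round_trip(self, tmp_path):
        from omicsvote.classify import FittedModel

        t = toy_table(n=30)
        model = fit_final(t, ModelSpec(kind="RF", hyperparams={"n_estimators": 30}))
        model.save(tmp_path / "rf.joblib")
        back = FittedModel.load(tmp_path / "rf.joblib")
        assert np.array_equal(model.predict(t), back.predict(t))
        assert np.allclose(model.predict_proba(t), back.predict_proba(t))

    def test_seeded_refit_is_deterministic(self):
        t = toy_table(n=30, separable=False)
        a = fit_final(t, ModelSpec(kind="RF", seed=7, hyperparams={"n_estimators": 30}))
        b = fit_final(t, ModelSpec(kind="RF", seed=7, hyperparams={"n_estimators": 30}))
        assert np.array_equal(a.predict(t), b.predict(t))

    def test_schema_mismatch_errors(self):
        t = toy_table(n=20)
        model = fit_final(t, ModelSpec(kind="DT"))
        with pytest.raises(ValueError, match="f1"):
            model.predict(t.subset_features(["f2"]))


def test_default_specs_cover_all_kinds():
    assert [s.kind for s in default_model_specs()] == ["LR", "DT", "KNN", "SVM", "RF"]
    with pytest.raises(ValueError):
        ModelSpec(kind="MLP")
    with pytest.raises(ValueError):
        ModelSpec(kind="KNN", hyperparams={"n_neighbors": 0})
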
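import numpy as np
import pandas as pd
import pytest

from omicsvote.classify import CVConfig, ModelSpec
from omicsvote.io import PEPTIDE, FeatureTable
from omicsvote.selection import (
    METHODS,
    SelectorConfig,
    chi2_statistic,
    consensus_score,
    features_at_threshold,
    pearson_matrix,
    run_all_methods,
    select_chi2,
    select_lr,
    select_pearson,
    select_rf,
    select_rfe,
    sweep_threshold,
)
from omicsvote.simulate import SyntheticSpec, generate_cohort


def make_table(columns: dict, y) -> FeatureTable:
    df = pd.DataFrame(columns, index=[f"s{i}" for i in range(len(y))])
    return FeatureTable(
        data=df.astype(float),
        labels=pd.Series(list(y), index=df.index),
        feature_kinds={c: PEPTIDE for c in df.columns},
    )


class TestPearsonMatrix:
    def test_perfect_positive(self):
        t = make_table({"x": [1, 2, 3], "y": [2, 4, 6]}, [0, 1, 1])
        assert pearson_matrix(t).R[0, 1] == pytest.approx(1.0)

    def test_perfect_negative(self):
        t = make_table({"x": [1, 2, 3], "y": [6, 4, 2]}, [0, 1, 1])
        assert pearson_matrix(t).R[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        t = make_table({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]}, [0, 0, 1, 1])
        assert pearson_matrix(t).R[0, 1] == pytest.approx(0.8)

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10, 10))
        t = make_table({f"f{j}": X[:, j] for j in range(10)}, rng.integers(0, 2, 10))
        R = pearson_matrix(t).R
        # independent oracle: explicit two-pass covariance then normalization
        mu = X.mean(axis=0)
        C = (X - mu).T @ (X - mu) / (X.shape[0] - 1)
        R_oracle = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
        assert np.abs(R - R_oracle).max() < 1e-10

    def test_constant_feature_r_zero_diag_one(self):
        t = make_table({"x": [1, 2, 3], "c": [5, 5, 5]}, [0, 1, 1])
        with pytest.warns(UserWarning, match="constant"):
            cm = pearson_matrix(t)
        assert cm.R[0, 1] == 0.0
        assert cm.R[1, 1] == 1.0

    def test_single_sample_errors(self):
        t = make_table({"x": [1.0], "y": [2.0]}, [1])
        with pytest.raises(ValueError, match="2 samples"):
            pearson_matrix(t)


class TestSelectPearson:
    def test_identical_features_pruned(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 10)
        sig = y + rng.normal(0, 0.3, 20)
        noise = rng.normal(size=20)
        t = make_table({"a": sig, "a_copy": sig, "b": noise}, y)
        cfg = SelectorConfig(k_per_method=2, pearson_redundancy_cutoff=0.9)
        chosen = select_pearson(t, cfg)
        assert len(chosen) == 2
        assert not {"a", "a_copy"} <= set(chosen)

    def test_uncorrelated_top_k_by_label_correlation(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 15)
        cols = {
            "strong": y + rng.normal(0, 0.2, 30),
            "medium": y + rng.normal(0, 1.0, 30),
            "weak": rng.normal(size=30),
            "none": rng.normal(size=30),
        }
        chosen = select_pearson(make_table(cols, y), SelectorConfig(k_per_method=3))
        assert chosen[0] == "strong"
        assert set(chosen) <= {"strong", "medium", "weak", "none"} and len(chosen) == 3

    def test_set_size_contract(self):
        cohort = generate_cohort(SyntheticSpec(n_pca=20, n_bph=20, n_peptides=12,
                                               clinical_params={}, seed=5))
        for k in (1, 5, 12, 50):
            cfg = SelectorConfig(k_per_method=k)
            assert len(select_pearson(cohort.table, cfg)) == min(k, 12)


class TestChiSquare:
    def test_independent_table_zero(self):
        assert chi2_statistic([[10, 10], [10, 10]]) == pytest.approx(0.0)

    def test_diagonal_table_forty(self):
        assert chi2_statistic([[20, 0], [0, 20]]) == pytest.approx(40.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            chi2_statistic([[1, -1], [0, 2]])

    def test_negative_feature_directs_to_normalization(self):
        t = make_table({"x": [-1, 0, 1]}, [0, 1, 1])
        with pytest.raises(ValueError, match="normaliz"):
            select_chi2(t, SelectorConfig(k_per_method=1))

    def test_nondiscriminative_feature_never_beats_discriminative(self):
        y = np.repeat([0, 1], 10)
        t = make_table({"flat": np.ones(20), "disc": y.astype(float)}, y)
        assert select_chi2(t, SelectorConfig(k_per_method=1)) == ["disc"]


class TestRFE:
    def test_pure_noise_eliminated_first(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 20)
        t = make_table(
            {"s1": y + rng.normal(0, 0.2, 40), "s2": 1 - y + rng.normal(0, 0.2, 40),
             "noise": rng.normal(size=40)},
            y,
        )
        selected, order = select_rfe(t, SelectorConfig(k_per_method=2), return_order=True)
        assert order[0] == "noise"
        assert set(selected) == {"s1", "s2"}

    def test_k_equals_n_features_identity(self):
        t = make_table({"a": [0, 1, 0, 1], "b": [1, 0, 1, 0]}, [0, 1, 0, 1])
        assert set(select_rfe(t, SelectorConfig(k_per_method=2))) == {"a", "b"}

    def test_k_too_large_errors(self):
        t = make_table({"a": [0, 1, 0, 1]}, [0, 1, 0, 1])
        with pytest.raises(ValueError):
            select_rfe(t, SelectorConfig(k_per_method=5))

    def test_elimination_order_matches_refit_oracle(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 25)
        X = rng.normal(size=(50, 5))
        X[:, 0] += 2.0 * y
        X[:, 3] += 1.0 * y
        names = [f"f{j}" for j in range(5)]
        t = make_table({n: X[:, j] for j, n in enumerate(names)}, y)
        _, order = select_rfe(t, SelectorConfig(k_per_method=1, seed=0), return_order=True)

        # oracle: refit after each single removal, dropping the min-|coef| feature
        remaining = list(range(5))
        oracle_order = []
        while len(remaining) > 1:
            lr = LogisticRegression(max_iter=5000, random_state=0)
            lr.fit(X[:, remaining], y)
            drop = remaining[int(np.argmin(np.abs(lr.coef_.ravel())))]
            oracle_order.append(names[drop])
            remaining.remove(drop)
        assert order == oracle_order


class TestEmbeddedSelectors:
    def test_rf_label_copy_has_top_importance(self):
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1], 15)
        t = make_table({"copy": y.astype(float), "n1": rng.normal(size=30),
                        "n2": rng.normal(size=30)}, y)
        assert select_rf(t, SelectorConfig(k_per_method=1, rf_n_trees=100))[0] == "copy"

    def test_rf_permuted_labels_importances_near_uniform(self):
        rng = np.random.default_rng(12)
        from sklearn.ensemble import RandomForestClassifier

        X = rng.normal(size=(100, 20))
        y = rng.permutation(np.repeat([0, 1], 50))
        rf = RandomForestClassifier(n_estimators=300, random_state=0)
        rf.fit(X, y)
        imp = rf.feature_importances_
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert imp.max() / imp.min() < 10  # no runaway importance under the null

    def test_lr_label_copy_has_largest_coefficient(self):
        rng = np.random.default_rng(13)
        y = np.repeat([0, 1], 15)
        t = make_table({"copy": y.astype(float), "n1": rng.normal(size=30)}, y)
        assert select_lr(t, SelectorConfig(k_per_method=1))[0] == "copy"

    def test_lr_l1_zeroes_noise_coefficients(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 20))
        y = rng.permutation(np.repeat([0, 1], 30)).astype(int)
        lr = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=0.05, max_iter=5000)
        lr.fit(X, y)
        assert (lr.coef_.ravel() == 0).sum() >= 10

    def test_lr_single_informative_toy(self):
        rng = np.random.default_rng(15)
        y = np.repeat([0, 1], 20)
        t = make_table({"inf": y + rng.normal(0, 0.3, 40), "a": rng.normal(size=40),
                        "b": rng.normal(size=40)}, y)
        assert select_lr(t, SelectorConfig(k_per_method=1)) == ["inf"]


class TestConsensus:
    def test_cardinalities(self):
        sets = {
            "pearson": ["a", "b"], "chi2": ["a"], "rfe": ["a", "c"],
            "rf": ["a", "b"], "lr": ["a", "c"],
        }
        scores = consensus_score(sets)
        assert scores == {"a": 5, "b": 2, "c": 2}

    def test_absent_feature_scores_zero(self):
        sets = {m: ["x"] for m in METHODS}
        assert consensus_score(sets).get("y", 0) == 0

    def test_missing_method_errors(self):
        sets = {m: ["x"] for m in METHODS[:-1]}
        with pytest.raises(ValueError, match="lr"):
            consensus_score(sets)

    @pytest.mark.parametrize("scores", [{"a": 5, "b": 3, "c": 1, "d": 0}])
    def test_threshold_monotonicity(self, scores):
        sets_by_thr = [set(features_at_threshold(scores, t)) for t in (5, 4, 3, 2, 1)]
        for strict, loose in zip(sets_by_thr, sets_by_thr[1:]):
            assert strict <= loose


class TestSweep:
    @pytest.fixture(scope="class")
    def planted(self):
        from omicsvote.preprocess import Preprocessor
        from omicsvote.simulate import SyntheticCohort

        cohort = generate_cohort(
            SyntheticSpec(n_pca=30, n_bph=30, n_peptides=30, n_informative=3,
                          effect_size_d=2.0, clinical_params={}, missing_rate=0.0, seed=21)
        )
        normalized = Preprocessor().fit_transform(cohort.table)
        return SyntheticCohort(table=normalized, planted=cohort.planted, spec=cohort.spec)

    def _specs(self):
        return [ModelSpec(kind=k, seed=0,
                          hyperparams={"n_estimators": 100} if k == "RF" else {})
                for k in ("LR", "DT", "KNN", "SVM", "RF")]

    def test_single_candidate_chosen_trivially(self, planted):
        cfg = SelectorConfig(k_per_method=5, candidate_thresholds=(3,), seed=0)
        sets = run_all_methods(planted.table, cfg)
        res = sweep_threshold(planted.table, sets, cfg, model_specs=self._specs(),
                              cv_config=CVConfig(k=4, seed=0))
        assert res.chosen_threshold == 3

    def test_tie_breaks_toward_stricter_threshold(self, planted):
        # rig the sets so thresholds 5 and 4 give the same feature set
        sets = {m: ["pep0001", "pep0002"] for m in METHODS}
        cfg = SelectorConfig(candidate_thresholds=(5, 4), seed=0)
        res = sweep_threshold(planted.table, sets, cfg, model_specs=self._specs(),
                              cv_config=CVConfig(k=4, seed=0))
        assert res.chosen_threshold == 5

    def test_all_empty_sets_error(self, planted):
        sets = {m: [] for m in METHODS}
        cfg = SelectorConfig(candidate_thresholds=(5,), seed=0)
        with pytest.raises(ValueError, match="empty"):
            sweep_threshold(planted.table, sets, cfg, model_specs=self._specs(),
                            cv_config=CVConfig(k=4, seed=0))

    def test_planted_features_reach_full_consensus(self, planted):
        cfg = SelectorConfig(k_per_method=5, seed=0)
        scores = consensus_score(run_all_methods(planted.table, cfg))
        top = features_at_threshold(scores, 5)
        assert set(planted.planted) <= set(top) or len(set(planted.planted) & set(top)) >= 2
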
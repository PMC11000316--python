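"""Classifier zoo, confusion-matrix metrics, and stratified k-fold
cross-validation.

Five model families are supported — logistic regression (LR), decision tree
(DT), k-nearest neighbours (KNN), RBF support-vector machine (SVM) and
random forest (RF) — each scored on AUC, accuracy, F1, sensitivity and
specificity with the prostate-cancer class (1) as positive. The AUC is the
rank-based (Mann-Whitney) area computed here directly; tests cross-check it
against the trapezoidal ROC area.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import FeatureTable
from .preprocess import Preprocessor

__all__ = [
    "MODEL_KINDS",
    "METRICS",
    "ModelSpec",
    "CVConfig",
    "CVReport",
    "FittedModel",
    "SingleClassError",
    "default_model_specs",
    "make_folds",
    "rank_auc",
    "confusion_metrics",
    "cross_validate",
    "fit_final",
]

MODEL_KINDS = ("LR", "DT", "KNN", "SVM", "RF")
METRICS = ("auc", "accuracy", "f1", "sensitivity", "specificity")


# scikit-learn 1.9 deprecates SVC(probability=True) in favour of an external
# calibration wrapper; the internal Platt scaling is exactly the calibrated
# score this package wants, so silence the migration notice.
warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)


class SingleClassError(ValueError):
    """AUC is undefined when y_true holds a single class."""


@dataclass
class ModelSpec:
    """One classifier kind plus its hyperparameters.

    Defaults: LR with L2 penalty and unit regularization; DT unrestricted
    depth; KNN with 5 Euclidean neighbours; SVM with RBF kernel, cost 1,
    gamma = 1/n_features and probability-calibrated scores; RF with 500
    trees. All seeded.
    """

    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")
        hp = self.hyperparams
        if self.kind == "SVM" and hp.get("gamma", 1.0) != "auto" and isinstance(
            hp.get("gamma", 1.0), (int, float)
        ) and hp.get("gamma", 1.0) <= 0:
            raise ValueError("SVM gamma must be positive")
        if self.kind == "KNN" and hp.get("n_neighbors", 5) < 1:
            raise ValueError("KNN neighbour count must be >= 1")

    def build(self):
        hp = dict(self.hyperparams)
        if self.kind == "LR":
            hp.setdefault("C", 1.0)
            hp.setdefault("max_iter", 5000)
            return LogisticRegression(random_state=self.seed, **hp)
        if self.kind == "DT":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        if self.kind == "KNN":
            hp.setdefault("n_neighbors", 5)
            return KNeighborsClassifier(**hp)
        if self.kind == "SVM":
            hp.setdefault("kernel", "rbf")
            hp.setdefault("C", 1.0)
            hp.setdefault("gamma", "auto")  # 1 / n_features
            hp.setdefault("probability", True)
            return SVC(random_state=self.seed, **hp)
        hp.setdefault("n_estimators", 500)
        hp.setdefault("n_jobs", 1)
        return RandomForestClassifier(random_state=self.seed, **hp)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(kind=k, seed=seed) for k in MODEL_KINDS]


@dataclass
class CVConfig:
    k: int = 10
    stratified: bool = True
    seed: int = 0
    fold_safe_preprocessing: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("fold count k must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CVConfig":
        return cls(**d)


def make_folds(table: FeatureTable, cv_config: CVConfig) -> list[np.ndarray]:
    """Deterministic (seeded) fold assignment: a list of k disjoint test-index
    arrays covering all samples; stratified folds keep per-fold class counts
    within 1 of proportionality."""
    n = table.n_samples
    if cv_config.k > n:
        raise ValueError(f"k={cv_config.k} exceeds n_samples={n}")
    y = table.y()
    if cv_config.stratified:
        counts = np.bincount(y, minlength=2)
        if (counts < cv_config.k).any():
            raise ValueError(
                f"stratified folds need >= k samples per class (counts {counts.tolist()}, "
                f"k={cv_config.k}); use a smaller k"
            )
        splitter = StratifiedKFold(n_splits=cv_config.k, shuffle=True, random_state=cv_config.seed)
    else:
        splitter = KFold(n_splits=cv_config.k, shuffle=True, random_state=cv_config.seed)
    return [test for _, test in splitter.split(np.zeros(n), y)]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Mann-Whitney AUC: probability a positive outranks a negative, ties at
    half weight (a constant score gives 0.5)."""
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC undefined: y_true holds a single class")
    ranks = rankdata(y_score)
    r_pos = ranks[y_true == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray | None = None
) -> dict[str, float]:
    """Five-metric bundle from hard calls and (optionally) scores, with the
    positive class encoded 1.

    Returns accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
    F1 = 2TP/(2TP+FP+FN), confusion counts, and AUC when ``y_score`` is
    given (raises :class:`SingleClassError` on single-class truth).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = len(y_true)
    out: dict[str, float] = {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan"),
    }
    if y_score is not None:
        out["auc"] = rank_auc(y_true, y_score)
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-model mean and sd of the five metrics over completed folds, plus
    the raw per-fold values and out-of-fold predictions."""

    model_kinds: list[str]
    fold_metrics: dict[str, list[dict[str, float]]]
    n_folds: int
    n_folds_completed: dict[str, int]
    oof_predictions: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    oof_probabilities: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    oof_true: np.ndarray | None = field(default=None, repr=False)
    oof_fold_ids: np.ndarray | None = field(default=None, repr=False)

    def mean_metric(self, kind: str, metric: str) -> float:
        vals = [m[metric] for m in self.fold_metrics[kind] if not np.isnan(m.get(metric, np.nan))]
        return float(np.mean(vals)) if vals else float("nan")

    def sd_metric(self, kind: str, metric: str) -> float:
        vals = [m[metric] for m in self.fold_metrics[kind] if not np.isnan(m.get(metric, np.nan))]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def best_model(self) -> str:
        return max(self.model_kinds, key=lambda k: (self.mean_metric(k, "auc"), k))

    def accuracies(self) -> dict[str, float]:
        return {k: self.mean_metric(k, "accuracy") for k in self.model_kinds}

    def summary_rows(self) -> list[dict]:
        rows = []
        for kind in self.model_kinds:
            row: dict = {"model": kind, "folds": self.n_folds_completed[kind]}
            for metric in METRICS:
                row[f"{metric}_mean"] = self.mean_metric(kind, metric)
                row[f"{metric}_sd"] = self.sd_metric(kind, metric)
            rows.append(row)
        return rows

    def to_dict(self) -> dict:
        return {
            "models": self.summary_rows(),
            "best_model": self.best_model,
            "n_folds": self.n_folds,
            "fold_metrics": {
                k: [{m: (None if np.isnan(v) else v) for m, v in fm.items()} for fm in folds]
                for k, folds in self.fold_metrics.items()
            },
        }


def cross_validate(
    table: FeatureTable,
    model_specs: Sequence[ModelSpec],
    cv_config: CVConfig,
    preprocessor: Preprocessor | None = None,
) -> CVReport:
    """Stratified k-fold assessment of each model spec.

    For every fold each model is fitted on the remaining folds and scored on
    the held-out one; the five metrics are averaged over completed folds.
    A degenerate training fold (single class) is skipped with a warning.
    With ``fold_safe_preprocessing`` and a ``preprocessor``, imputation
    means / encodings / ranges are refitted inside each training fold.
    """
    if not model_specs:
        raise ValueError("cross_validate: empty model list")
    folds = make_folds(table, cv_config)
    n = table.n_samples
    y_all = table.y()
    # report rows are keyed by kind; duplicate specs get suffixed names
    kinds: list[str] = []
    seen: dict[str, int] = {}
    for m in model_specs:
        seen[m.kind] = seen.get(m.kind, 0) + 1
        kinds.append(m.kind if seen[m.kind] == 1 else f"{m.kind}#{seen[m.kind]}")

    fold_metrics: dict[str, list[dict[str, float]]] = {k: [] for k in kinds}
    completed = {k: 0 for k in kinds}
    oof_pred = {k: np.full(n, -1, dtype=int) for k in kinds}
    oof_prob = {k: np.full(n, np.nan) for k in kinds}
    fold_ids = np.full(n, -1, dtype=int)

    fold_safe = cv_config.fold_safe_preprocessing and preprocessor is not None
    for fold_idx, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        if len(np.unique(y_all[train_idx])) < 2:
            warnings.warn(f"fold {fold_idx}: single-class training set; fold skipped")
            continue
        fold_ids[test_idx] = fold_idx

        if fold_safe:
            pp = Preprocessor(config=preprocessor.config)
            train_tab = pp.fit_transform(table.subset_samples([table.sample_ids[i] for i in train_idx]))
            test_tab = pp.transform(table.subset_samples([table.sample_ids[i] for i in test_idx]))
            X_train, X_test = train_tab.to_matrix(), test_tab.to_matrix()
            y_train = train_tab.y()
        else:
            X = table.to_matrix()
            X_train, X_test = X[train_idx], X[test_idx]
            y_train = y_all[train_idx]
        y_test = y_all[test_idx]

        for spec, name in zip(model_specs, kinds):
            est = spec.build()
            est.fit(X_train, y_train)
            pred = np.asarray(est.predict(X_test), dtype=int)
            prob = _positive_scores(est, X_test)
            oof_pred[name][test_idx] = pred
            oof_prob[name][test_idx] = prob
            try:
                metrics = confusion_metrics(y_test, pred, prob)
            except SingleClassError:
                metrics = confusion_metrics(y_test, pred)
                metrics["auc"] = float("nan")
            fold_metrics[name].append(metrics)
            completed[name] += 1

    return CVReport(
        model_kinds=kinds,
        fold_metrics=fold_metrics,
        n_folds=cv_config.k,
        n_folds_completed=completed,
        oof_predictions=oof_pred,
        oof_probabilities=oof_prob,
        oof_true=y_all,
        oof_fold_ids=fold_ids,
    )


def _positive_scores(est, X: np.ndarray) -> np.ndarray:
    """Positive-class probability, or a monotone [0,1] map of the decision
    value for margin-only models (AUC is invariant to the map)."""
    if hasattr(est, "predict_proba"):
        classes = list(est.classes_)
        return np.asarray(est.predict_proba(X))[:, classes.index(1)]
    from scipy.special import expit

    return expit(np.asarray(est.decision_function(X)))


# ---------------------------------------------------------------------------
# Final fit
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A trained estimator bound to its feature schema; picklable and
    reusable on new tables."""

    spec: ModelSpec
    estimator: object
    feature_names: list[str]

    def _matrix(self, table: FeatureTable) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.feature_names]
        if missing:
            raise ValueError(f"table lacks fitted feature(s) {missing}")
        return table.to_matrix(self.feature_names)

    def predict(self, table: FeatureTable) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._matrix(table)), dtype=int)

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        return _positive_scores(self.estimator, self._matrix(table))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "FittedModel":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a FittedModel")
        return obj


def fit_final(table: FeatureTable, model_spec: ModelSpec) -> FittedModel:
    """Fit one model on every row of the (preprocessed) table."""
    est = model_spec.build()
    est.fit(table.to_matrix(), table.y())
    return FittedModel(spec=model_spec, estimator=est, feature_names=table.feature_names)
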
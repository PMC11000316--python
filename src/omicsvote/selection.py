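"""Five-method consensus feature selection.

Each of five rankers — Pearson correlation with redundancy pruning,
chi-square scoring, recursive feature elimination, random-forest impurity
importance, and L1 logistic-regression weights — nominates ``k_per_method``
features. A feature's consensus score (0-5) counts how many methods
nominated it; the final panel keeps features whose score reaches a
threshold, chosen by sweeping candidate thresholds and cross-validating the
restricted table.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.feature_selection import RFE
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier

from .io import FeatureTable

__all__ = [
    "METHODS",
    "CorrelationMatrix",
    "SelectorConfig",
    "SelectionResult",
    "pearson_matrix",
    "chi2_statistic",
    "select_pearson",
    "select_chi2",
    "select_rfe",
    "select_rf",
    "select_lr",
    "run_all_methods",
    "consensus_score",
    "sweep_threshold",
]

METHODS = ("pearson", "chi2", "rfe", "rf", "lr")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson coefficient matrix R with the covariance matrix C it derives
    from, R[i,j] = C[i,j] / sqrt(C[i,i] * C[j,j])."""

    feature_names: list[str]
    R: np.ndarray
    C: np.ndarray


@dataclass
class SelectorConfig:
    k_per_method: int | None = None  # None -> max(10, ceil(n_features / 10))
    pearson_redundancy_cutoff: float = 0.9
    rfe_step: int = 1
    candidate_thresholds: tuple[int, ...] = (5, 4, 3, 2, 1)
    rf_n_trees: int = 500
    sweep_rule: str = "one_se"  # or "max": strict argmax of the objective
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pearson_redundancy_cutoff <= 1.0:
            raise ValueError("pearson_redundancy_cutoff must lie in (0, 1]")
        if any(t not in (1, 2, 3, 4, 5) for t in self.candidate_thresholds):
            raise ValueError("candidate thresholds must be integers in 1..5")
        if self.rfe_step < 1:
            raise ValueError("rfe_step must be >= 1")
        if self.sweep_rule not in ("one_se", "max"):
            raise ValueError(f"unknown sweep_rule {self.sweep_rule!r}")

    def resolve_k(self, n_features: int) -> int:
        k = self.k_per_method if self.k_per_method is not None else max(10, math.ceil(n_features / 10))
        if k < 1:
            raise ValueError("k_per_method must be >= 1")
        return min(k, n_features)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidate_thresholds"] = list(self.candidate_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SelectorConfig":
        d = dict(d)
        if "candidate_thresholds" in d:
            d["candidate_thresholds"] = tuple(d["candidate_thresholds"])
        return cls(**d)


@dataclass
class SelectionResult:
    per_method_sets: dict[str, list[str]]
    consensus_score: dict[str, int]
    chosen_threshold: int
    selected_features: list[str]
    sweep_trace: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_method_sets": {m: list(s) for m, s in self.per_method_sets.items()},
            "consensus_score": dict(self.consensus_score),
            "chosen_threshold": int(self.chosen_threshold),
            "selected_features": list(self.selected_features),
            "sweep_trace": self.sweep_trace,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            per_method_sets=d["per_method_sets"],
            consensus_score={k: int(v) for k, v in d["consensus_score"].items()},
            chosen_threshold=int(d["chosen_threshold"]),
            selected_features=d["selected_features"],
            sweep_trace=d.get("sweep_trace", []),
        )


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def pearson_matrix(table: FeatureTable) -> CorrelationMatrix:
    """Feature-feature Pearson matrix from the covariance matrix.

    Constant features get r = 0 against everything (diagonal 1 by
    convention) with a warning; fewer than 2 samples is an error.
    """
    X = table.to_matrix()
    if X.shape[0] < 2:
        raise ValueError("pearson_matrix needs at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("pearson_matrix: missing values present; impute first")
    C = np.cov(X, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    d = np.diag(C).copy()
    constant = d <= 0
    if constant.any():
        warnings.warn(
            f"pearson_matrix: constant feature(s) "
            f"{[table.feature_names[i] for i in np.flatnonzero(constant)]}; r set to 0"
        )
    denom = np.sqrt(np.where(constant, 1.0, d))
    R = C / np.outer(denom, denom)
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    return CorrelationMatrix(feature_names=table.feature_names, R=R, C=C)


def _label_correlation(table: FeatureTable) -> np.ndarray:
    X = table.to_matrix()
    y = table.y().astype(float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = xc.std(axis=0, ddof=1)
    sy = yc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / ((X.shape[0] - 1) * sx * sy)
    return np.nan_to_num(r, nan=0.0)


def select_pearson(table: FeatureTable, cfg: SelectorConfig) -> list[str]:
    """Rank features by |correlation with the label|, then scan the ranking
    keeping a feature only if its |r| with every already-kept feature stays
    at or below the redundancy cutoff; top-up from the pruned ranking if the
    scan keeps fewer than k."""
    k = cfg.resolve_k(table.n_features)
    names = table.feature_names
    corr = pearson_matrix(table)
    label_r = np.abs(_label_correlation(table))
    order = np.argsort(-label_r, kind="stable")
    kept: list[int] = []
    pruned: list[int] = []
    for idx in order:
        if len(kept) >= k:
            break
        if any(abs(corr.R[idx, j]) > cfg.pearson_redundancy_cutoff for j in kept):
            pruned.append(idx)
            continue
        kept.append(idx)
    for idx in pruned:  # pad to the contracted set size
        if len(kept) >= k:
            break
        kept.append(idx)
    return [names[i] for i in kept]


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

def chi2_statistic(observed) -> float:
    """Classic contingency-table chi-square: sum over cells of
    (O - E)^2 / E with expectations from the row/column margins."""
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2:
        raise ValueError("observed must be a 2-D contingency table")
    if (O < 0).any():
        raise ValueError("counts must be nonnegative")
    total = O.sum()
    if total == 0:
        return 0.0
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    mask = E > 0
    return float((((O - E) ** 2)[mask] / E[mask]).sum())


def select_chi2(table: FeatureTable, cfg: SelectorConfig) -> list[str]:
    """Top-k features by the nonnegative-feature chi-square score: the
    statistic of each feature's class-wise value sums against the class
    prior. Negative values are an error — normalize to [0, 1] first."""
    X = table.to_matrix()
    if (X < 0).any():
        raise ValueError("select_chi2 needs nonnegative features; run min-max normalization first")
    stats, _ = _sk_chi2(X, table.y())
    stats = np.nan_to_num(stats, nan=0.0)
    k = cfg.resolve_k(table.n_features)
    order = np.argsort(-stats, kind="stable")[:k]
    return [table.feature_names[i] for i in order]


# ---------------------------------------------------------------------------
# Wrapper methods
# ---------------------------------------------------------------------------

def _rfe_estimator(cfg: SelectorConfig) -> LogisticRegression:
    return LogisticRegression(max_iter=5000, random_state=cfg.seed)


def select_rfe(
    table: FeatureTable, cfg: SelectorConfig, return_order: bool = False
) -> list[str] | tuple[list[str], list[str]]:
    """Recursive feature elimination with a logistic-regression base
    estimator: refit, drop the ``rfe_step`` lowest-|weight| features, repeat
    until k remain. Optionally also return the elimination order (first
    eliminated first)."""
    k = cfg.resolve_k(table.n_features)
    if (cfg.k_per_method or 0) > table.n_features:
        raise ValueError(
            f"k_per_method={cfg.k_per_method} exceeds n_features={table.n_features}"
        )
    rfe = RFE(_rfe_estimator(cfg), n_features_to_select=k, step=cfg.rfe_step)
    rfe.fit(table.to_matrix(), table.y())
    names = np.array(table.feature_names)
    selected = names[rfe.support_].tolist()
    if not return_order:
        return selected
    # ranking_ is 1 for kept features and grows toward earlier elimination
    order = names[np.argsort(-rfe.ranking_, kind="stable")]
    eliminated = [n for n in order if n not in set(selected)]
    return selected, eliminated


def select_rf(table: FeatureTable, cfg: SelectorConfig) -> list[str]:
    """Top-k features by mean impurity-decrease importance of a seeded
    random forest (importances sum to 1)."""
    rf = RandomForestClassifier(n_estimators=cfg.rf_n_trees, random_state=cfg.seed, n_jobs=1)
    rf.fit(table.to_matrix(), table.y())
    imp = rf.feature_importances_
    k = cfg.resolve_k(table.n_features)
    order = np.argsort(-imp, kind="stable")[:k]
    return [table.feature_names[i] for i in order]


def select_lr(table: FeatureTable, cfg: SelectorConfig) -> list[str]:
    """Top-k features by |coefficient| of an L1-penalized logistic
    regression (sparse weights prune redundant features)."""
    lr = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=1.0, random_state=cfg.seed, max_iter=5000
    )
    lr.fit(table.to_matrix(), table.y())
    coefs = np.abs(lr.coef_.ravel())
    k = cfg.resolve_k(table.n_features)
    order = np.argsort(-coefs, kind="stable")[:k]
    return [table.feature_names[i] for i in order]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def run_all_methods(table: FeatureTable, cfg: SelectorConfig) -> dict[str, list[str]]:
    return {
        "pearson": select_pearson(table, cfg),
        "chi2": select_chi2(table, cfg),
        "rfe": select_rfe(table, cfg),
        "rf": select_rf(table, cfg),
        "lr": select_lr(table, cfg),
    }


def consensus_score(per_method_sets: Mapping[str, Sequence[str]]) -> dict[str, int]:
    """score[f] = number of methods whose nominated set contains f (0..5).

    Features nominated by no method are absent from the mapping (score 0).
    """
    missing = set(METHODS) - set(per_method_sets)
    if missing:
        raise ValueError(f"consensus_score: missing method set(s) {sorted(missing)}")
    scores: dict[str, int] = {}
    for method in METHODS:
        for f in set(per_method_sets[method]):
            scores[f] = scores.get(f, 0) + 1
    return scores


def features_at_threshold(scores: Mapping[str, int], threshold: int) -> list[str]:
    return sorted(f for f, s in scores.items() if s >= threshold)


def sweep_threshold(
    table: FeatureTable,
    per_method_sets: Mapping[str, Sequence[str]],
    cfg: SelectorConfig,
    model_specs=None,
    cv_config=None,
    objective: str = "best_auc",
) -> SelectionResult:
    """Choose the consensus threshold by cross-validated performance.

    For each candidate threshold (non-empty feature sets only) the
    classification stage is cross-validated on the restricted table and
    scored by the best model's mean AUC (``objective`` may also be
    ``mean_auc``). Under the default ``one_se`` rule the chosen threshold is
    the strictest one whose AUC lies within one standard error (over folds,
    at the best threshold) of the maximum — a parsimony rule in the spirit
    of regularization-path selection, so that chance-level AUC wiggles from
    extra noise features cannot drag the panel larger. ``sweep_rule="max"``
    takes the strict argmax instead; exact ties always break toward the
    stricter threshold.
    """
    from .classify import CVConfig, cross_validate, default_model_specs

    scores = consensus_score(per_method_sets)
    if cv_config is None:
        cv_config = CVConfig(seed=cfg.seed)
    if model_specs is None:
        model_specs = default_model_specs(seed=cfg.seed)

    trace: list[dict] = []
    evaluated: list[tuple[int, float, float]] = []  # (threshold, auc, se)
    for thr in sorted(set(cfg.candidate_thresholds), reverse=True):
        feats = features_at_threshold(scores, thr)
        if not feats:
            trace.append({"threshold": thr, "n_features": 0, "auc": None, "note": "empty set"})
            continue
        report = cross_validate(table.subset_features(feats), model_specs, cv_config)
        if objective == "mean_auc":
            auc = float(np.mean([report.mean_metric(k, "auc") for k in report.model_kinds]))
            se = float(np.mean([report.sd_metric(k, "auc") for k in report.model_kinds]))
        else:
            auc = report.mean_metric(report.best_model, "auc")
            se = report.sd_metric(report.best_model, "auc")
        n_done = max(report.n_folds_completed.get(report.best_model, 1), 1)
        se /= np.sqrt(n_done)
        trace.append(
            {"threshold": thr, "n_features": len(feats), "auc": auc, "auc_se": se,
             "best_model": report.best_model}
        )
        evaluated.append((thr, auc, se))
    if not evaluated:
        raise ValueError("sweep_threshold: every candidate threshold gave an empty feature set")
    best_thr, best_auc, best_se = max(evaluated, key=lambda t: (t[1], t[0]))
    if cfg.sweep_rule == "one_se":
        margin = best_auc - best_se
        chosen = max(thr for thr, auc, _ in evaluated if auc >= margin - 1e-12)
    else:
        chosen = best_thr
    return SelectionResult(
        per_method_sets={m: list(per_method_sets[m]) for m in METHODS},
        consensus_score=scores,
        chosen_threshold=chosen,
        selected_features=features_at_threshold(scores, chosen),
        sweep_trace=trace,
    )
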
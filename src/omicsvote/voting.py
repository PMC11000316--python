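"""Hard (majority) and soft (accuracy-weighted) ensemble voting.

Hard voting takes the majority of the five models' 0/1 calls; soft voting
averages positive-class probabilities with weights proportional to each
model's cross-validated accuracy and calls PCa when the weighted score
reaches 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classify import FittedModel
from .io import EnsemblePrediction, FeatureTable

__all__ = [
    "VoteWeights",
    "hard_vote",
    "soft_vote",
    "validate_holdout",
    "count_correct",
    "ensemble_cv_metrics",
]


@dataclass(frozen=True)
class VoteWeights:
    """Nonnegative per-model weights normalized to sum 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty weight mapping")
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("weights must be nonnegative")
        total = vals.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        object.__setattr__(
            self, "weights", {k: float(v) / float(total) for k, v in self.weights.items()}
        )

    @classmethod
    def from_accuracies(cls, accuracies: Mapping[str, float]) -> "VoteWeights":
        return cls(weights=dict(accuracies))

    @classmethod
    def uniform(cls, kinds: Sequence[str]) -> "VoteWeights":
        return cls(weights={k: 1.0 for k in kinds})

    def aligned(self, kinds: Sequence[str]) -> np.ndarray:
        missing = [k for k in kinds if k not in self.weights]
        if missing:
            raise ValueError(f"no weight for model(s) {missing}")
        return np.array([self.weights[k] for k in kinds], dtype=float)


def hard_vote(per_model_labels: Sequence[int], tie_rule: str | None = None) -> int:
    """Majority label of the individual 0/1 calls.

    An even split raises unless ``tie_rule`` is ``"positive"`` or
    ``"negative"`` (5 models cannot tie).
    """
    labels = np.asarray(per_model_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("hard_vote: no model labels")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError(f"hard_vote: labels must be 0/1, got {labels.tolist()}")
    ones = int(labels.sum())
    zeros = labels.size - ones
    if ones > zeros:
        return 1
    if zeros > ones:
        return 0
    if tie_rule == "positive":
        return 1
    if tie_rule == "negative":
        return 0
    raise ValueError("hard_vote: even split with no tie rule configured")


def soft_vote(
    per_model_probabilities: Sequence[float], weights: VoteWeights | Sequence[float] | None = None
) -> tuple[int, float]:
    """Weighted mean of positive-class probabilities; label 1 iff the score
    reaches 0.5 (ties break toward PCa)."""
    probs = np.asarray(per_model_probabilities, dtype=float)
    if probs.size == 0:
        raise ValueError("soft_vote: no probabilities")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError(f"soft_vote: probabilities outside [0, 1]: {probs.tolist()}")
    if weights is None:
        w = np.full(probs.size, 1.0 / probs.size)
    elif isinstance(weights, VoteWeights):
        w = np.array(list(weights.weights.values()), dtype=float)
        if w.size != probs.size:
            raise ValueError("weight count does not match probability count")
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    score = float(np.dot(w, probs))
    return (1 if score >= 0.5 else 0), score


def validate_holdout(
    models: Sequence[FittedModel],
    weights: VoteWeights,
    holdout_table: FeatureTable,
) -> EnsemblePrediction:
    """Score a held-out table (already transformed with the stored training
    preprocessing) with every model and both ensemble strategies."""
    kinds = [m.spec.kind for m in models]
    if len(set(kinds)) != len(kinds):
        raise ValueError(f"duplicate model kinds: {kinds}")
    n = holdout_table.n_samples
    if n == 0:
        return EnsemblePrediction(
            sample_ids=[], y_true=np.array([], dtype=int),
            hard_labels=np.array([], dtype=int), soft_labels=np.array([], dtype=int),
            soft_scores=np.array([], dtype=float),
        )
    for m in models:
        missing = [f for f in m.feature_names if f not in holdout_table.feature_names]
        extra = [f for f in holdout_table.feature_names if f not in m.feature_names]
        if missing:
            raise ValueError(
                f"holdout schema mismatch for {m.spec.kind}: missing {missing}, extra {extra}"
            )
    labels = {m.spec.kind: m.predict(holdout_table) for m in models}
    probs = {m.spec.kind: m.predict_proba(holdout_table) for m in models}
    w = weights.aligned(kinds)
    hard = np.array([hard_vote([labels[k][i] for k in kinds]) for i in range(n)], dtype=int)
    soft_pairs = [soft_vote([probs[k][i] for k in kinds], w) for i in range(n)]
    return EnsemblePrediction(
        sample_ids=holdout_table.sample_ids,
        y_true=holdout_table.y() if len(holdout_table.labels.dropna()) == n else None,
        hard_labels=hard,
        soft_labels=np.array([p[0] for p in soft_pairs], dtype=int),
        soft_scores=np.array([p[1] for p in soft_pairs], dtype=float),
        per_model_labels=labels,
        per_model_probs=probs,
        label_encoding=dict(holdout_table.label_encoding),
    )


def count_correct(preds: EnsemblePrediction, strategy: str) -> int:
    """Number of samples whose hard- or soft-vote call equals the true label."""
    if preds.y_true is None:
        raise ValueError("count_correct needs true labels")
    if strategy == "hard":
        calls = preds.hard_labels
    elif strategy == "soft":
        calls = preds.soft_labels
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected 'hard' or 'soft'")
    return int((calls == preds.y_true).sum())


def ensemble_cv_metrics(report, weights: VoteWeights | None = None) -> dict[str, dict[str, float]]:
    """Ensemble assessment from a CVReport's out-of-fold predictions.

    Each sample's hard and soft calls are formed from the models' held-out
    predictions in its own fold; weights default to the models' mean CV
    accuracies. Returns the confusion-metric bundle per strategy.
    """
    from .classify import confusion_metrics

    kinds = report.model_kinds
    if weights is None:
        weights = VoteWeights.from_accuracies(report.accuracies())
    w = weights.aligned(kinds)
    scored = report.oof_fold_ids >= 0
    y = report.oof_true[scored]
    label_mat = np.stack([report.oof_predictions[k][scored] for k in kinds])
    prob_mat = np.stack([report.oof_probabilities[k][scored] for k in kinds])
    hard = np.array([hard_vote(label_mat[:, i]) for i in range(label_mat.shape[1])])
    soft_scores = w @ prob_mat
    soft = (soft_scores >= 0.5).astype(int)
    return {
        "hard": confusion_metrics(y, hard),
        "soft": confusion_metrics(y, soft, soft_scores),
    }
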
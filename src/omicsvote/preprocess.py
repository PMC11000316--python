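"""Data preparation: sparse-row/column dropping, class-conditional mean
imputation, ordinal encoding of categoricals, and min-max scaling to [0, 1].

The default policy mirrors a whole-dataset preparation step: imputation means
and scaling ranges are fitted on the full labelled table. A ``fold_safe``
mode refits them inside each training fold instead (see
:mod:`omicsvote.classify`), which avoids information leaking from held-out
samples into the transform parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CLINICAL_CATEGORICAL, FeatureTable

__all__ = [
    "PreprocessConfig",
    "Preprocessor",
    "drop_sparse",
    "drop_irrelevant",
    "impute_class_mean",
    "encode_categoricals",
    "minmax_normalize",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    sample_max_missing_frac: float = 0.5
    feature_max_missing_frac: float = 0.5
    irrelevant_columns: list[str] = field(default_factory=list)
    imputation_mode: str = "class_conditional_mean"  # or "global_mean"
    normalize: bool = True
    max_categorical_levels: int = 20

    def __post_init__(self) -> None:
        for name in ("sample_max_missing_frac", "feature_max_missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.imputation_mode not in ("class_conditional_mean", "global_mean"):
            raise ValueError(f"unknown imputation_mode {self.imputation_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


def drop_sparse(table: FeatureTable, cfg: PreprocessConfig) -> FeatureTable:
    """Remove samples, then features, whose missing fraction exceeds the
    configured thresholds. Row/column order is otherwise preserved."""
    miss = table.missing_mask
    row_frac = miss.mean(axis=1)
    keep_rows = row_frac <= cfg.sample_max_missing_frac
    dropped_rows = table.data.index[~keep_rows].tolist()
    if not keep_rows.any():
        raise ValueError("all samples exceed the missing-fraction threshold; empty table")
    if dropped_rows:
        logger.info(
            "drop_sparse: removed %d sample(s) with missing fraction > %.3g: %s",
            len(dropped_rows), cfg.sample_max_missing_frac, dropped_rows,
        )
    out = table.subset_samples(table.data.index[keep_rows])

    col_frac = out.missing_mask.mean(axis=0)
    keep_cols = col_frac <= cfg.feature_max_missing_frac
    dropped_cols = out.data.columns[~keep_cols].tolist()
    if dropped_cols:
        logger.info(
            "drop_sparse: removed %d feature(s) with missing fraction > %.3g: %s",
            len(dropped_cols), cfg.feature_max_missing_frac, dropped_cols,
        )
    return out.subset_features(out.data.columns[keep_cols])


def drop_irrelevant(table: FeatureTable, cfg: PreprocessConfig) -> FeatureTable:
    """Remove the configured irrelevant columns (e.g. previous-surgery flags).
    Unknown names warn instead of failing."""
    names = list(cfg.irrelevant_columns)
    unknown = [n for n in names if n not in table.feature_names]
    if unknown:
        warnings.warn(f"drop_irrelevant: columns not in table, ignored: {unknown}")
    keep = [f for f in table.feature_names if f not in set(names)]
    if len(keep) == table.n_features:
        return table.copy()
    return table.subset_features(keep)


def _class_means(table: FeatureTable, feature: str) -> tuple[dict[int, float], float]:
    col = table.data[feature].astype(float)
    overall = col.dropna()
    if overall.empty:
        raise ValueError(f"feature {feature!r} is entirely missing; cannot impute")
    global_mean = float(overall.mean())
    means: dict[int, float] = {}
    for code in (0, 1):
        vals = col[table.labels == code].dropna()
        if vals.empty:
            warnings.warn(
                f"impute_class_mean: feature {feature!r} entirely missing in class "
                f"{code}; falling back to the global mean"
            )
            means[code] = global_mean
        else:
            means[code] = float(vals.mean())
    return means, global_mean


def impute_class_mean(table: FeatureTable, cfg: PreprocessConfig | None = None) -> FeatureTable:
    """Replace each missing numeric cell with the mean of the non-missing
    values of the same feature within the same diagnosis class (or the global
    mean in ``global_mean`` mode)."""
    mode = cfg.imputation_mode if cfg is not None else "class_conditional_mean"
    out = table.copy()
    for feature in table.numeric_features():
        col = out.data[feature].astype(float)
        if not col.isna().any():
            continue
        means, global_mean = _class_means(table, feature)
        if mode == "global_mean":
            fill = pd.Series(global_mean, index=col.index)
        else:
            fill = out.labels.map(means).astype(float)
        out.data[feature] = col.fillna(fill)
    return out


def encode_categoricals(
    table: FeatureTable, mappings: dict[str, dict[str, int]] | None = None,
    max_levels: int = 20,
) -> tuple[FeatureTable, dict[str, dict[str, int]]]:
    """Map each categorical feature to integer codes 0..(levels-1) in sorted
    level order. Pass stored ``mappings`` to re-apply a fitted encoding; an
    unseen level then raises."""
    out = table.copy()
    fitted: dict[str, dict[str, int]] = {}
    for feature in table.feature_names:
        if table.feature_kinds[feature] != CLINICAL_CATEGORICAL:
            continue
        col = out.data[feature]
        observed = sorted({str(v) for v in col.dropna()})
        if mappings is not None and feature in mappings:
            mapping = mappings[feature]
            unseen = [v for v in observed if v not in mapping]
            if unseen:
                raise ValueError(f"unseen level(s) {unseen} in column {feature!r}")
        else:
            if len(observed) > max_levels:
                raise ValueError(
                    f"categorical column {feature!r} has {len(observed)} levels "
                    f"(> {max_levels}); refusing ordinal encoding"
                )
            mapping = {lvl: i for i, lvl in enumerate(observed)}
        fitted[feature] = mapping
        out.data[feature] = pd.array(
            [mapping[str(v)] if pd.notna(v) else np.nan for v in col], dtype=float
        )
        out.feature_kinds[feature] = "clinical_numeric"
    return out, fitted


def minmax_normalize(
    table: FeatureTable, ranges: dict[str, tuple[float, float]] | None = None
) -> tuple[FeatureTable, dict[str, tuple[float, float]]]:
    """Scale each numeric feature to [0, 1] via (x - min) / (max - min).

    Run after imputation (missing cells are an error). With ``ranges`` given,
    re-applies a fitted transform and clips held-out values into [0, 1];
    constant features map to 0.
    """
    out = table.copy()
    fitted: dict[str, tuple[float, float]] = {}
    for feature in out.numeric_features():
        col = out.data[feature].astype(float)
        if col.isna().any():
            raise ValueError(
                f"minmax_normalize: column {feature!r} still has missing values; impute first"
            )
        if ranges is not None and feature in ranges:
            lo, hi = ranges[feature]
        else:
            lo, hi = float(col.min()), float(col.max())
        fitted[feature] = (lo, hi)
        if hi > lo:
            out.data[feature] = ((col - lo) / (hi - lo)).clip(0.0, 1.0)
        else:
            out.data[feature] = 0.0
    return out, fitted


@dataclass
class Preprocessor:
    """Fit/transform wrapper over the full preparation chain.

    ``fit_transform`` runs drop-irrelevant -> drop-sparse -> impute ->
    encode -> normalize on a labelled table and stores imputation means,
    categorical mappings and min/max ranges; ``transform`` re-applies them to
    new (possibly unlabelled) data, imputing with the global training mean
    since class membership is unknown at prediction time.
    """

    config: PreprocessConfig = field(default_factory=PreprocessConfig)
    imputation_means_: dict[str, float] | None = None
    encodings_: dict[str, dict[str, int]] | None = None
    ranges_: dict[str, tuple[float, float]] | None = None
    feature_names_: list[str] | None = None

    def fit_transform(self, table: FeatureTable) -> FeatureTable:
        t = drop_irrelevant(table, self.config)
        t = drop_sparse(t, self.config)
        # global means recorded before imputation, for transform-time fill
        self.imputation_means_ = {
            f: float(t.data[f].astype(float).dropna().mean()) for f in t.numeric_features()
        }
        t = impute_class_mean(t, self.config)
        t, self.encodings_ = encode_categoricals(t, max_levels=self.config.max_categorical_levels)
        if self.config.normalize:
            t, self.ranges_ = minmax_normalize(t)
        else:
            self.ranges_ = None
        self.feature_names_ = t.feature_names
        return t

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.feature_names_ is None:
            raise RuntimeError("Preprocessor not fitted")
        missing = [f for f in self.feature_names_ if f not in table.feature_names]
        if missing:
            raise ValueError(f"transform: table lacks fitted feature(s) {missing}")
        t = table.subset_features(self.feature_names_)
        for feature in list(t.numeric_features()):
            col = t.data[feature].astype(float)
            if col.isna().any():
                t.data[feature] = col.fillna(self.imputation_means_[feature])
        t, _ = encode_categoricals(t, mappings=self.encodings_ or {})
        if self.ranges_ is not None:
            t, _ = minmax_normalize(t, ranges=self.ranges_)
        return t

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "imputation_means": self.imputation_means_,
            "encodings": self.encodings_,
            "ranges": self.ranges_,
            "feature_names": self.feature_names_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        p = cls(config=PreprocessConfig.from_dict(d["config"]))
        p.imputation_means_ = d["imputation_means"]
        p.encodings_ = d["encodings"]
        p.ranges_ = (
            {k: tuple(v) for k, v in d["ranges"].items()} if d["ranges"] is not None else None
        )
        p.feature_names_ = d["feature_names"]
        return p

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Preprocessor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
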
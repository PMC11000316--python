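"""Feature-table data model and delimited-text I/O.

The on-disk dialect is a plain CSV with a header row: one row per patient
sample, an identifier column, a diagnosis label column (``BPH`` / ``PCa``,
any casing), clinical columns, and a block of peptide-intensity columns.
Missing values are the literal ``NaN`` (any casing) or an empty cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLINICAL_NUMERIC",
    "CLINICAL_CATEGORICAL",
    "PEPTIDE",
    "DEFAULT_CLINICAL_COLUMNS",
    "FeatureTable",
    "ColumnStats",
    "EnsemblePrediction",
    "LabelValueError",
    "IntegrityError",
    "CellParseError",
    "read_feature_table",
    "write_feature_table",
    "column_stats",
    "write_prediction_report",
    "read_prediction_report",
]

CLINICAL_NUMERIC = "clinical_numeric"
CLINICAL_CATEGORICAL = "clinical_categorical"
PEPTIDE = "peptide"
_KINDS = (CLINICAL_NUMERIC, CLINICAL_CATEGORICAL, PEPTIDE)

#: Column names treated as numeric clinical features when no kind map is given.
#: Matching is case- and punctuation-insensitive (``Total PSA`` == ``TotalPsa``).
DEFAULT_CLINICAL_COLUMNS = (
    "Age",
    "ProstateGlandSize",
    "TotalPsa",
    "PsaFree",
    "FreePsa",
    "FTratio",
    "ProPsa",
)

LABEL_ENCODING = {"BPH": 0, "PCa": 1}

_MISSING_LITERALS = {"", "nan"}


class LabelValueError(ValueError):
    """A label cell holds something other than a BPH/PCa variant."""


class IntegrityError(ValueError):
    """Structural inconsistency in a table (e.g. duplicate sample ids)."""


class CellParseError(ValueError):
    """A numeric column holds a non-numeric, non-missing cell."""


def _canon(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


@dataclass
class FeatureTable:
    """Samples-by-features matrix with per-feature kinds and 0/1 labels.

    ``data`` is a :class:`pandas.DataFrame` indexed by sample id; numeric
    columns are floats with ``NaN`` as the canonical missing marker,
    categorical clinical columns may hold strings. ``labels`` is aligned to
    ``data.index`` and encoded BPH -> 0, PCa -> 1.
    """

    data: pd.DataFrame
    labels: pd.Series
    feature_kinds: dict[str, str]
    label_encoding: dict[str, int] = field(default_factory=lambda: dict(LABEL_ENCODING))
    id_column: str = "Id"
    label_column: str = "Disease"

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        self.labels = self.labels.reindex(self.data.index)
        self._validate()

    def _validate(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise IntegrityError(f"duplicate feature names: {dupes}")
        unknown = set(self.feature_kinds) - set(self.data.columns)
        missing = set(self.data.columns) - set(self.feature_kinds)
        if unknown or missing:
            raise IntegrityError(
                f"feature_kinds out of sync with columns (extra={sorted(unknown)}, "
                f"missing={sorted(missing)})"
            )
        bad_kind = {f: k for f, k in self.feature_kinds.items() if k not in _KINDS}
        if bad_kind:
            raise IntegrityError(f"unknown feature kinds: {bad_kind}")
        if len(self.labels) and not self.labels.isin([0, 1]).all():
            bad = self.labels[~self.labels.isin([0, 1])]
            raise IntegrityError(f"labels must be 0/1 after encoding, got {bad.tolist()}")

    # -- basic views ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_names(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def numeric_features(self) -> list[str]:
        return [f for f in self.feature_names if self.feature_kinds[f] != CLINICAL_CATEGORICAL]

    def to_matrix(self, features: Sequence[str] | None = None) -> np.ndarray:
        """Dense float matrix (requires all-numeric selected features)."""
        cols = list(features) if features is not None else self.feature_names
        return self.data[cols].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def subset_features(self, features: Sequence[str]) -> "FeatureTable":
        features = list(features)
        return FeatureTable(
            data=self.data[features].copy(),
            labels=self.labels.copy(),
            feature_kinds={f: self.feature_kinds[f] for f in features},
            label_encoding=dict(self.label_encoding),
            id_column=self.id_column,
            label_column=self.label_column,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        ids = [str(s) for s in sample_ids]
        return FeatureTable(
            data=self.data.loc[ids].copy(),
            labels=self.labels.loc[ids].copy(),
            feature_kinds=dict(self.feature_kinds),
            label_encoding=dict(self.label_encoding),
            id_column=self.id_column,
            label_column=self.label_column,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            data=self.data.copy(),
            labels=self.labels.copy(),
            feature_kinds=dict(self.feature_kinds),
            label_encoding=dict(self.label_encoding),
            id_column=self.id_column,
            label_column=self.label_column,
        )


@dataclass(frozen=True)
class ColumnStats:
    """Per-class descriptive summary of one numeric feature (native units)."""

    feature_name: str
    per_class: dict[str, dict[str, float]]  # class name -> {mean, std, min, q25, q50, q75, max, n}


def _normalize_label(raw: str, row_id: str) -> int:
    key = raw.strip().lower()
    if key == "bph":
        return 0
    if key == "pca":
        return 1
    raise LabelValueError(f"unknown label {raw!r} for sample {row_id!r} (expected BPH or PCa)")


def read_feature_table(
    path,
    label_column: str = "Disease",
    id_column: str = "Id",
    kind_map: Mapping[str, str] | None = None,
    clinical_columns: Iterable[str] = DEFAULT_CLINICAL_COLUMNS,
    categorical_columns: Iterable[str] = (),
    delimiter: str = ",",
) -> FeatureTable:
    """Read a feature table from delimited text.

    ``NaN`` literals (any casing) and empty cells become missing. Labels are
    matched case-insensitively against BPH/PCa and encoded 0/1. Column kinds
    come from ``kind_map`` when given; otherwise columns named in
    ``clinical_columns`` (case/punctuation-insensitive) are clinical-numeric,
    ``categorical_columns`` are clinical-categorical, and the rest are
    peptide intensities.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in (id_column, label_column):
        if col not in raw.columns:
            raise IntegrityError(f"required column {col!r} not in header {list(raw.columns)}")

    ids = raw[id_column].astype(str).str.strip()
    if ids.duplicated().any():
        raise IntegrityError(f"duplicate sample id(s): {ids[ids.duplicated()].tolist()}")

    labels = pd.Series(
        [_normalize_label(v, i) for v, i in zip(raw[label_column], ids)],
        index=ids,
        dtype=int,
        name=label_column,
    )

    feature_cols = [c for c in raw.columns if c not in (id_column, label_column)]
    clinical_canon = {_canon(c) for c in clinical_columns}
    categorical_canon = {_canon(c) for c in categorical_columns}

    kinds: dict[str, str] = {}
    for col in feature_cols:
        if kind_map is not None and col in kind_map:
            kinds[col] = kind_map[col]
        elif _canon(col) in categorical_canon:
            kinds[col] = CLINICAL_CATEGORICAL
        elif _canon(col) in clinical_canon:
            kinds[col] = CLINICAL_NUMERIC
        else:
            kinds[col] = PEPTIDE

    data = pd.DataFrame(index=ids)
    for col in feature_cols:
        cells = raw[col].astype(str).str.strip()
        is_missing = cells.str.lower().isin(_MISSING_LITERALS)
        if kinds[col] == CLINICAL_CATEGORICAL:
            vals = cells.where(~is_missing.to_numpy(), other=None)
            data[col] = vals.to_numpy(dtype=object)
        else:
            numeric = pd.to_numeric(cells.where(~is_missing.to_numpy(), other=None), errors="coerce")
            bad = numeric.isna().to_numpy() & ~is_missing.to_numpy()
            if bad.any():
                r = int(np.flatnonzero(bad)[0])
                raise CellParseError(
                    f"non-numeric value {cells.iloc[r]!r} in numeric column {col!r}, "
                    f"sample {ids.iloc[r]!r}"
                )
            data[col] = numeric.to_numpy(dtype=float)

    return FeatureTable(
        data=data,
        labels=labels,
        feature_kinds=kinds,
        id_column=id_column,
        label_column=label_column,
    )


def write_feature_table(table: FeatureTable, path, delimiter: str = ",") -> None:
    """Write a table back to the CSV dialect consumed by :func:`read_feature_table`."""
    inv = {v: k for k, v in table.label_encoding.items()}
    out = table.data.copy()
    out.insert(0, table.id_column, table.data.index)
    out[table.label_column] = [inv[v] for v in table.labels]
    # keep label column right after clinical columns if present, else append; the
    # reader does not care about position, so append is fine.
    out.to_csv(path, sep=delimiter, index=False, na_rep="NaN")


def column_stats(table: FeatureTable, feature: str) -> ColumnStats:
    """Per-class mean/std/quartile summary over non-missing cells.

    Raises ``ValueError`` when every cell of a class is missing. A class with
    a single observation reports std 0.0.
    """
    if feature not in table.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    if table.feature_kinds[feature] == CLINICAL_CATEGORICAL:
        raise ValueError(f"feature {feature!r} is categorical; stats need a numeric column")
    col = table.data[feature].astype(float)
    per_class: dict[str, dict[str, float]] = {}
    for cls_name, code in table.label_encoding.items():
        present = table.labels == code
        if not present.any():
            continue
        vals = col[present].dropna().to_numpy()
        if vals.size == 0:
            raise ValueError(f"stats undefined: all {feature!r} cells missing for class {cls_name}")
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        per_class[cls_name] = {
            "mean": float(np.mean(vals)),
            "std": 0.0 if vals.size == 1 else float(np.std(vals, ddof=1)),
            "min": float(np.min(vals)),
            "q25": float(q25),
            "q50": float(q50),
            "q75": float(q75),
            "max": float(np.max(vals)),
            "n": int(vals.size),
        }
    return ColumnStats(feature_name=feature, per_class=per_class)


@dataclass
class EnsemblePrediction:
    """Per-sample model calls and ensemble calls (the validation-report shape).

    ``per_model_labels`` / ``per_model_probs`` map model kind to an array
    aligned with ``sample_ids``; they are optional because a report read back
    from disk carries only the ensemble columns.
    """

    sample_ids: list[str]
    y_true: np.ndarray | None
    hard_labels: np.ndarray
    soft_labels: np.ndarray
    soft_scores: np.ndarray | None = None
    per_model_labels: dict[str, np.ndarray] | None = None
    per_model_probs: dict[str, np.ndarray] | None = None
    label_encoding: dict[str, int] = field(default_factory=lambda: dict(LABEL_ENCODING))

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("hard_labels", "soft_labels"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (n,):
                raise IntegrityError(f"{name} length {arr.shape} != n_samples {n}")
            if len(arr) and not np.isin(arr, [0, 1]).all():
                raise IntegrityError(f"{name} must be 0/1")
            setattr(self, name, arr)
        if self.y_true is not None:
            self.y_true = np.asarray(self.y_true, dtype=int)
        if self.soft_scores is not None:
            self.soft_scores = np.asarray(self.soft_scores, dtype=float)
            if len(self.soft_scores) and (
                self.soft_scores.min() < 0 or self.soft_scores.max() > 1
            ):
                raise IntegrityError("soft scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnsemblePrediction):
            return NotImplemented
        same_true = (
            (self.y_true is None and other.y_true is None)
            or (
                self.y_true is not None
                and other.y_true is not None
                and np.array_equal(self.y_true, other.y_true)
            )
        )
        return (
            self.sample_ids == other.sample_ids
            and same_true
            and np.array_equal(self.hard_labels, other.hard_labels)
            and np.array_equal(self.soft_labels, other.soft_labels)
        )


def write_prediction_report(preds: EnsemblePrediction, path) -> None:
    """Write the four-column validation report (PatientId, DiagnosedDisease,
    SoftVoting, HardVoting)."""
    if len(preds) == 0:
        raise ValueError("empty prediction set; nothing to report")
    inv = {v: k for k, v in preds.label_encoding.items()}
    df = pd.DataFrame(
        {
            "PatientId": preds.sample_ids,
            "DiagnosedDisease": (
                [inv[v] for v in preds.y_true] if preds.y_true is not None else [""] * len(preds)
            ),
            "SoftVoting": preds.soft_labels,
            "HardVoting": preds.hard_labels,
        }
    )
    df.to_csv(path, index=False)


def read_prediction_report(path) -> EnsemblePrediction:
    df = pd.read_csv(path, dtype={"PatientId": str}, keep_default_na=False)
    required = {"PatientId", "DiagnosedDisease", "SoftVoting", "HardVoting"}
    if not required <= set(df.columns):
        raise IntegrityError(f"prediction report must have columns {sorted(required)}")
    labels = df["DiagnosedDisease"].astype(str)
    y_true = None
    if (labels.str.strip() != "").all():
        y_true = np.array([_normalize_label(v, i) for v, i in zip(labels, df["PatientId"])])
    return EnsemblePrediction(
        sample_ids=df["PatientId"].astype(str).tolist(),
        y_true=y_true,
        hard_labels=df["HardVoting"].astype(int).to_numpy(),
        soft_labels=df["SoftVoting"].astype(int).to_numpy(),
    )
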
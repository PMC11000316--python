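"""Synthetic case-control cohort generator.

Emulates a prostate case-control study: clinical features drawn per class
from truncated normals with published-style summary parameters (mean, sd,
min, max per diagnosis), a block of right-skewed (log-normal) peptide
intensities with a planted informative subset shifted between classes on
the log scale, and completely-at-random missingness in the clinical columns
that real exports lose most often (gland size and the PSA family).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CLINICAL_NUMERIC, PEPTIDE, FeatureTable

__all__ = [
    "ClassParams",
    "SyntheticSpec",
    "SyntheticCohort",
    "default_clinical_params",
    "generate_cohort",
    "generate_holdout",
    "self_test",
]


@dataclass(frozen=True)
class ClassParams:
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.min > self.max:
            raise ValueError(f"infeasible truncation: min {self.min} > max {self.max}")


def default_clinical_params() -> dict[str, dict[str, ClassParams]]:
    """Per-class clinical distribution parameters for a prostate cohort:
    age in years, gland volume in ml, total/free PSA in mg/l, and the
    free/total PSA ratio (taken at face value despite its odd published
    scale relative to example records)."""
    return {
        "Age": {
            "PCa": ClassParams(66.0, 6.23, 47.0, 77.0),
            "BPH": ClassParams(69.0, 6.49, 56.0, 81.0),
        },
        "ProstateGlandSize": {
            "PCa": ClassParams(39.78, 14.26, 20.0, 75.0),
            "BPH": ClassParams(71.67, 35.86, 30.0, 173.0),
        },
        "TotalPsa": {
            "PCa": ClassParams(10.33, 11.47, 3.01, 58.40),
            "BPH": ClassParams(4.02, 5.09, 0.07, 21.86),
        },
        "PsaFree": {
            "PCa": ClassParams(18.41, 10.88, 1.00, 62.00),
            "BPH": ClassParams(39.22, 19.83, 0.10, 79.00),
        },
        "FTratio": {
            "PCa": ClassParams(1.73, 1.36, 0.52, 5.65),
            "BPH": ClassParams(1.49, 1.95, 0.05, 9.43),
        },
    }


#: Clinical columns subject to missingness (where real exports are sparse).
DEFAULT_MISSING_COLUMNS = ("ProstateGlandSize", "TotalPsa", "PsaFree", "FTratio")


@dataclass
class SyntheticSpec:
    """Generative parameters for one cohort.

    ``n_pca``/``n_bph`` are the class sizes; ``n_peptides`` peptides are
    log-normal with ``n_informative`` of them shifted by ``effect_size_d``
    log-scale standard deviations in the PCa class; ``missing_rate`` applies
    MCAR to ``missing_columns``. Pass ``clinical_params={}`` for a
    peptide-only design. ``derive_ft_ratio`` computes FTratio as
    PsaFree / TotalPsa instead of sampling it independently.
    """

    n_pca: int = 67
    n_bph: int = 54
    clinical_params: dict[str, dict[str, ClassParams]] = field(
        default_factory=default_clinical_params
    )
    n_peptides: int = 100
    n_informative: int | None = None  # None -> min(5, n_peptides)
    effect_size_d: float = 1.5
    peptide_log_mean: float = 9.0
    peptide_log_sd: float = 1.0
    missing_rate: float = 0.1
    missing_columns: tuple[str, ...] = DEFAULT_MISSING_COLUMNS
    derive_ft_ratio: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pca < 1 or self.n_bph < 1:
            raise ValueError("class counts must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_informative is None:
            self.n_informative = min(5, self.n_peptides)
        if self.n_informative > self.n_peptides:
            raise ValueError("n_informative cannot exceed n_peptides")
        for feat, per_class in self.clinical_params.items():
            for cls, p in per_class.items():
                if not isinstance(p, ClassParams):
                    per_class[cls] = ClassParams(**p)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["missing_columns"] = list(self.missing_columns)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["clinical_params"] = {
            f: {c: ClassParams(**p) for c, p in per.items()}
            for f, per in d.get("clinical_params", {}).items()
        }
        if "missing_columns" in d:
            d["missing_columns"] = tuple(d["missing_columns"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A generated table together with the planted-informative peptide list."""

    table: FeatureTable
    planted: list[str]
    spec: SyntheticSpec


def _truncnorm_draw(rng: np.random.Generator, p: ClassParams, n: int) -> np.ndarray:
    if p.sd == 0:
        return np.full(n, p.mean)
    a = (p.min - p.mean) / p.sd
    b = (p.max - p.mean) / p.sd
    return stats.truncnorm.rvs(a, b, loc=p.mean, scale=p.sd, size=n, random_state=rng)


def _generate(spec: SyntheticSpec, rng: np.random.Generator, id_prefix: str) -> SyntheticCohort:
    n = spec.n_pca + spec.n_bph
    y = np.concatenate([np.ones(spec.n_pca, dtype=int), np.zeros(spec.n_bph, dtype=int)])
    perm = rng.permutation(n)
    y = y[perm]
    ids = [f"{id_prefix}{i + 1}" for i in range(n)]

    data = pd.DataFrame(index=pd.Index(ids, name="Id"))
    kinds: dict[str, str] = {}

    # iterate in sorted name order so the draw sequence (hence the cohort) is
    # independent of dict insertion order after config round-trips
    for feat in sorted(spec.clinical_params):
        per_class = spec.clinical_params[feat]
        vals = np.empty(n)
        for cls, code in (("PCa", 1), ("BPH", 0)):
            mask = y == code
            vals[mask] = _truncnorm_draw(rng, per_class[cls], int(mask.sum()))
        data[feat] = vals
        kinds[feat] = CLINICAL_NUMERIC
    if spec.derive_ft_ratio and {"TotalPsa", "PsaFree"} <= set(data.columns):
        data["FTratio"] = data["PsaFree"] / data["TotalPsa"]
        kinds["FTratio"] = CLINICAL_NUMERIC

    pep_names = [f"pep{i + 1:04d}" for i in range(spec.n_peptides)]
    planted = pep_names[: spec.n_informative]
    log_int = rng.normal(spec.peptide_log_mean, spec.peptide_log_sd, size=(n, spec.n_peptides))
    shift = spec.effect_size_d * spec.peptide_log_sd
    log_int[:, : spec.n_informative] += shift * y[:, None]
    pep = pd.DataFrame(np.exp(log_int), index=data.index, columns=pep_names)
    data = pd.concat([data, pep], axis=1)
    kinds.update({name: PEPTIDE for name in pep_names})

    if spec.missing_rate > 0:
        for col in spec.missing_columns:
            if col in data.columns:
                mask = rng.random(n) < spec.missing_rate
                data.loc[mask, col] = np.nan

    table = FeatureTable(
        data=data,
        labels=pd.Series(y, index=data.index, name="Disease"),
        feature_kinds=kinds,
    )
    return SyntheticCohort(table=table, planted=planted, spec=spec)


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Deterministically generate a labelled cohort from the spec's seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    return _generate(spec, rng, id_prefix="id")


def generate_holdout(spec: SyntheticSpec, n: int) -> SyntheticCohort:
    """Draw ``n`` validation samples from the same generative process on a
    disjoint seed stream; class sizes follow the spec's class ratio
    (rounded, each class >= 1 when n >= 2)."""
    if n == 0:
        empty = SyntheticSpec.from_dict(spec.to_dict())
        cohort = generate_cohort(empty)
        table = cohort.table.subset_samples([])
        return SyntheticCohort(table=table, planted=cohort.planted, spec=spec)
    frac = spec.n_pca / (spec.n_pca + spec.n_bph)
    n_pca = min(max(int(round(n * frac)), 1), max(n - 1, 1))
    hold = SyntheticSpec.from_dict(spec.to_dict())
    hold.n_pca = n_pca
    hold.n_bph = max(n - n_pca, 1)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    cohort = _generate(hold, rng, id_prefix="hid")
    if cohort.table.n_samples > n:  # n == 1 pads the minority class; trim back
        cohort = SyntheticCohort(
            table=cohort.table.subset_samples(cohort.table.sample_ids[:n]),
            planted=cohort.planted, spec=spec,
        )
    return cohort


def self_test(spec: SyntheticSpec, cohort: SyntheticCohort, z: float = 4.0) -> dict:
    """Diagnostics comparing the generated table against its own spec.

    Per clinical feature and class, the sample mean must sit within
    ``z`` standard errors of the truncated-normal mean (the sd check uses the
    truncated moments too); the overall missing count must fall in a
    ``z``-sigma binomial band. Returns per-check pass/fail plus a global
    ``passed`` flag.
    """
    table = cohort.table
    y = table.y()
    checks: list[dict] = []

    for feat, per_class in spec.clinical_params.items():
        if spec.derive_ft_ratio and feat == "FTratio":
            continue
        for cls, code in (("PCa", 1), ("BPH", 0)):
            p = per_class[cls]
            vals = table.data[feat][y == code].dropna().to_numpy()
            if vals.size < 2 or p.sd == 0:
                continue
            a, b = (p.min - p.mean) / p.sd, (p.max - p.mean) / p.sd
            tmean, tvar = stats.truncnorm.stats(a, b, loc=p.mean, scale=p.sd, moments="mv")
            se = np.sqrt(float(tvar) / vals.size)
            ok = abs(vals.mean() - float(tmean)) <= z * se
            checks.append(
                {"check": f"mean[{feat},{cls}]", "observed": float(vals.mean()),
                 "expected": float(tmean), "tol": z * se, "passed": bool(ok)}
            )
            in_bounds = bool((vals >= p.min - 1e-9).all() and (vals <= p.max + 1e-9).all())
            checks.append(
                {"check": f"bounds[{feat},{cls}]", "observed": [float(vals.min()), float(vals.max())],
                 "expected": [p.min, p.max], "tol": 0.0, "passed": in_bounds}
            )

    miss_cols = [c for c in spec.missing_columns if c in table.feature_names]
    if miss_cols:
        n_cells = table.n_samples * len(miss_cols)
        n_miss = int(table.missing_mask[miss_cols].to_numpy().sum())
        sd = np.sqrt(n_cells * spec.missing_rate * (1 - spec.missing_rate))
        ok = abs(n_miss - n_cells * spec.missing_rate) <= max(z * sd, 1.0)
        checks.append(
            {"check": "missing_rate", "observed": n_miss / n_cells,
             "expected": spec.missing_rate, "tol": max(z * sd, 1.0) / n_cells, "passed": bool(ok)}
        )

    return {"passed": all(c["passed"] for c in checks), "checks": checks}
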
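"""End-to-end orchestration: the :class:`ConsensusPipeline` model object and
reproducible staged runs.

The library surface follows the model/results convention: build a
``ConsensusPipeline`` from a :class:`~omicsvote.io.FeatureTable` (or a
DataFrame / CSV), call :meth:`~ConsensusPipeline.fit`, and get a
:class:`PipelineResults` carrying the selected panel, per-model
cross-validation metrics, fitted models, voting weights, a ``summary()``
table and ``predict()`` for held-out cohorts. The stage functions below the
class are the file-based equivalents the CLI wires together; ``run_all``
chains them so staged and one-shot runs are the same code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    CVConfig,
    CVReport,
    FittedModel,
    ModelSpec,
    cross_validate,
    default_model_specs,
    fit_final,
)
from .io import (
    DEFAULT_CLINICAL_COLUMNS,
    EnsemblePrediction,
    FeatureTable,
    read_feature_table,
    write_feature_table,
    write_prediction_report,
)
from .preprocess import PreprocessConfig, Preprocessor
from .selection import SelectionResult, SelectorConfig, run_all_methods, sweep_threshold
from .simulate import SyntheticCohort, SyntheticSpec, generate_cohort, generate_holdout
from .voting import VoteWeights, count_correct, validate_holdout

__all__ = [
    "PipelineConfig",
    "ConsensusPipeline",
    "PipelineResults",
    "stage_seed",
    "run_all",
    "stage_simulate",
    "stage_preprocess",
    "stage_select",
    "stage_train",
    "stage_vote",
]

_STAGES = {"simulate": 0, "selection": 1, "cv": 2, "models": 3, "holdout": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a single global seed out to a per-stage seed (counter-based, so
    stages can be rerun independently yet reproducibly)."""
    ss = np.random.SeedSequence(global_seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``input_path`` or
    ``synthetic`` must be set."""

    input_path: str | None = None
    synthetic: SyntheticSpec | None = None
    label_column: str = "Disease"
    id_column: str = "Id"
    clinical_columns: list[str] = field(default_factory=lambda: list(DEFAULT_CLINICAL_COLUMNS))
    categorical_columns: list[str] = field(default_factory=list)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    model_kinds: list[str] = field(default_factory=lambda: ["LR", "DT", "KNN", "SVM", "RF"])
    cv: CVConfig = field(default_factory=CVConfig)
    weight_scheme: str = "cv_accuracy"  # or "uniform"
    holdout_path: str | None = None
    holdout_n: int = 0  # synthetic holdout size (0 = none)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must be set")
        if not self.model_kinds:
            raise ValueError("model list must not be empty")
        if self.weight_scheme not in ("cv_accuracy", "uniform"):
            raise ValueError(f"unknown weight_scheme {self.weight_scheme!r}")

    def model_specs(self) -> list[ModelSpec]:
        seed = stage_seed(self.seed, "models")
        return [ModelSpec(kind=k, seed=seed) for k in self.model_kinds]

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "label_column": self.label_column,
            "id_column": self.id_column,
            "clinical_columns": list(self.clinical_columns),
            "categorical_columns": list(self.categorical_columns),
            "preprocess": self.preprocess.to_dict(),
            "selector": self.selector.to_dict(),
            "model_kinds": list(self.model_kinds),
            "cv": self.cv.to_dict(),
            "weight_scheme": self.weight_scheme,
            "holdout_path": self.holdout_path,
            "holdout_n": self.holdout_n,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticSpec.from_dict(d["synthetic"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig.from_dict(d["preprocess"])
        if "selector" in d and isinstance(d["selector"], dict):
            d["selector"] = SelectorConfig.from_dict(d["selector"])
        if "cv" in d and isinstance(d["cv"], dict):
            d["cv"] = CVConfig.from_dict(d["cv"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ConsensusPipeline:
    """Consensus-selection + ensemble-voting classifier for a labelled
    clinical/peptide table.

    Parameters
    ----------
    table:
        Raw labelled :class:`FeatureTable` (missing values allowed).
    preprocess, selector, cv:
        Stage configurations; defaults reproduce the whole-dataset
        preparation policy with a 10-fold stratified assessment.
    model_specs:
        The classifier kinds to train; default LR/DT/KNN/SVM/RF.
    weight_scheme:
        ``"cv_accuracy"`` (soft-vote weights from each model's mean CV
        accuracy) or ``"uniform"``.
    seed:
        Global seed, fanned out per stage.
    """

    def __init__(
        self,
        table: FeatureTable,
        preprocess: PreprocessConfig | None = None,
        selector: SelectorConfig | None = None,
        model_specs: list[ModelSpec] | None = None,
        cv: CVConfig | None = None,
        weight_scheme: str = "cv_accuracy",
        seed: int = 0,
    ) -> None:
        self.table = table
        self.preprocess_config = preprocess or PreprocessConfig()
        self.selector_config = selector or SelectorConfig()
        self.cv_config = cv or CVConfig()
        self.seed = seed
        self.selector_config.seed = stage_seed(seed, "selection")
        self.cv_config.seed = stage_seed(seed, "cv")
        self.model_specs = model_specs or default_model_specs(seed=stage_seed(seed, "models"))
        if weight_scheme not in ("cv_accuracy", "uniform"):
            raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
        self.weight_scheme = weight_scheme

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "Disease",
        id_column: str = "Id",
        clinical_columns=DEFAULT_CLINICAL_COLUMNS,
        categorical_columns=(),
        **kwargs,
    ) -> "ConsensusPipeline":
        import io as _io

        buf = _io.StringIO()
        df.to_csv(buf, index=False, na_rep="NaN")
        buf.seek(0)
        table = read_feature_table(
            buf,
            label_column=label_column,
            id_column=id_column,
            clinical_columns=clinical_columns,
            categorical_columns=categorical_columns,
        )
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path, **read_kwargs_and_kwargs) -> "ConsensusPipeline":
        read_keys = {"label_column", "id_column", "clinical_columns", "categorical_columns", "delimiter"}
        read_kwargs = {k: v for k, v in read_kwargs_and_kwargs.items() if k in read_keys}
        kwargs = {k: v for k, v in read_kwargs_and_kwargs.items() if k not in read_keys}
        return cls(read_feature_table(path, **read_kwargs), **kwargs)

    def fit(self) -> "PipelineResults":
        preprocessor = Preprocessor(config=self.preprocess_config)
        processed = preprocessor.fit_transform(self.table)
        per_method = run_all_methods(processed, self.selector_config)
        selection = sweep_threshold(
            processed, per_method, self.selector_config,
            model_specs=self.model_specs, cv_config=self.cv_config,
        )
        restricted = processed.subset_features(selection.selected_features)
        cv_report = cross_validate(restricted, self.model_specs, self.cv_config)
        models = [fit_final(restricted, spec) for spec in self.model_specs]
        if self.weight_scheme == "uniform":
            weights = VoteWeights.uniform([m.kind for m in self.model_specs])
        else:
            weights = VoteWeights.from_accuracies(cv_report.accuracies())
        return PipelineResults(
            pipeline=self,
            preprocessor=preprocessor,
            selection=selection,
            cv_report=cv_report,
            models=models,
            weights=weights,
        )


@dataclass
class PipelineResults:
    """Fitted state of a :class:`ConsensusPipeline` run."""

    pipeline: ConsensusPipeline
    preprocessor: Preprocessor
    selection: SelectionResult
    cv_report: CVReport
    models: list[FittedModel]
    weights: VoteWeights

    @property
    def selected_features(self) -> list[str]:
        return self.selection.selected_features

    @property
    def best_model(self) -> str:
        return self.cv_report.best_model

    def predict(self, table: FeatureTable) -> EnsemblePrediction:
        """Transform a raw held-out table with the stored preprocessing
        parameters and score it with every model plus both voting
        strategies."""
        transformed = self.preprocessor.transform(table)
        restricted = transformed.subset_features(self.selected_features)
        return validate_holdout(self.models, self.weights, restricted)

    def roc_coordinates(self, kind: str) -> pd.DataFrame:
        """Empirical ROC of a model's out-of-fold CV scores (fpr, tpr,
        threshold)."""
        from sklearn.metrics import roc_curve

        scored = self.cv_report.oof_fold_ids >= 0
        y = self.cv_report.oof_true[scored]
        s = self.cv_report.oof_probabilities[kind][scored]
        fpr, tpr, thr = roc_curve(y, s)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    def plot_roc(self, ax=None):
        """ROC curves of all models from out-of-fold scores (needs
        matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for kind in self.cv_report.model_kinds:
            coords = self.roc_coordinates(kind)
            auc = self.cv_report.mean_metric(kind, "auc")
            ax.plot(coords.fpr, coords.tpr, label=f"{kind} (CV AUC {auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate (1 - specificity)")
        ax.set_ylabel("True positive rate (sensitivity)")
        ax.legend(loc="lower right")
        return ax

    def summary(self) -> str:
        """Human-readable report: panel, per-model CV metrics, weights."""
        lines = [
            "Consensus selection + ensemble voting",
            "=" * 64,
            f"Samples: {self.pipeline.table.n_samples}   "
            f"features in: {self.pipeline.table.n_features}   "
            f"selected: {len(self.selected_features)} "
            f"(consensus threshold {self.selection.chosen_threshold})",
            f"Panel: {', '.join(self.selected_features[:12])}"
            + (" ..." if len(self.selected_features) > 12 else ""),
            "",
            f"{'model':<6}{'AUC':>12}{'Accuracy':>14}{'F1':>12}{'Sens':>12}{'Spec':>12}",
            "-" * 68,
        ]
        for kind in self.cv_report.model_kinds:
            r = self.cv_report
            lines.append(
                f"{kind:<6}"
                f"{r.mean_metric(kind, 'auc'):>7.3f}±{r.sd_metric(kind, 'auc'):<5.2f}"
                f"{r.mean_metric(kind, 'accuracy'):>8.3f}±{r.sd_metric(kind, 'accuracy'):<5.2f}"
                f"{r.mean_metric(kind, 'f1'):>7.3f}±{r.sd_metric(kind, 'f1'):<5.2f}"
                f"{r.mean_metric(kind, 'sensitivity'):>7.3f}±{r.sd_metric(kind, 'sensitivity'):<5.2f}"
                f"{r.mean_metric(kind, 'specificity'):>7.3f}±{r.sd_metric(kind, 'specificity'):<5.2f}"
            )
        lines += [
            "-" * 68,
            f"Best model by mean CV AUC: {self.best_model}",
            "Soft-vote weights: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.weights.weights.items()),
        ]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.selection.to_json(outdir / "selection.json")
        with open(outdir / "cv_report.json", "w") as fh:
            json.dump(self.cv_report.to_dict(), fh, indent=2, sort_keys=True)
        self.preprocessor.save(outdir / "preprocessor.json")
        (outdir / "models").mkdir(exist_ok=True)
        for m in self.models:
            m.save(outdir / "models" / f"{m.spec.kind}.joblib")
        with open(outdir / "weights.json", "w") as fh:
            json.dump(self.weights.weights, fh, indent=2, sort_keys=True)
        for kind in self.cv_report.model_kinds:
            self.roc_coordinates(kind).to_csv(outdir / f"roc_{kind}.csv", index=False)


# ---------------------------------------------------------------------------
# Staged, file-based execution (CLI backbone)
# ---------------------------------------------------------------------------

def _load_table(config: PipelineConfig, path) -> FeatureTable:
    return read_feature_table(
        path,
        label_column=config.label_column,
        id_column=config.id_column,
        clinical_columns=config.clinical_columns,
        categorical_columns=config.categorical_columns,
    )


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    if config.synthetic is None:
        raise ValueError("stage simulate needs a synthetic spec in the config")
    spec = SyntheticSpec.from_dict(config.synthetic.to_dict())
    spec.seed = stage_seed(config.seed, "simulate")
    cohort = generate_cohort(spec)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(cohort.table, outdir / "cohort.csv")
    with open(outdir / "planted.json", "w") as fh:
        json.dump(cohort.planted, fh, indent=2)
    arts = ["cohort.csv", "planted.json"]
    if config.holdout_n > 0:
        hold = generate_holdout(spec, config.holdout_n)
        write_feature_table(hold.table, outdir / "holdout.csv")
        arts.append("holdout.csv")
    return {"stage": "simulate", "artifacts": arts, "n_samples": cohort.table.n_samples}


def stage_preprocess(config: PipelineConfig, outdir: Path, input_csv) -> dict:
    table = _load_table(config, input_csv)
    pp = Preprocessor(config=config.preprocess)
    processed = pp.fit_transform(table)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(processed, outdir / "preprocessed.csv")
    pp.save(outdir / "preprocessor.json")
    return {
        "stage": "preprocess",
        "artifacts": ["preprocessed.csv", "preprocessor.json"],
        "rows_in": table.n_samples, "rows_out": processed.n_samples,
        "features_in": table.n_features, "features_out": processed.n_features,
        "fold_safe": config.cv.fold_safe_preprocessing,
    }


def stage_select(config: PipelineConfig, outdir: Path, preprocessed_csv) -> dict:
    table = _load_table(config, preprocessed_csv)
    sel_cfg = SelectorConfig.from_dict(config.selector.to_dict())
    sel_cfg.seed = stage_seed(config.seed, "selection")
    cv_cfg = CVConfig.from_dict(config.cv.to_dict())
    cv_cfg.seed = stage_seed(config.seed, "cv")
    per_method = run_all_methods(table, sel_cfg)
    result = sweep_threshold(
        table, per_method, sel_cfg, model_specs=config.model_specs(), cv_config=cv_cfg
    )
    outdir.mkdir(parents=True, exist_ok=True)
    result.to_json(outdir / "selection.json")
    return {
        "stage": "select", "artifacts": ["selection.json"],
        "chosen_threshold": result.chosen_threshold,
        "n_selected": len(result.selected_features),
    }


def stage_train(config: PipelineConfig, outdir: Path, preprocessed_csv, selection_json) -> dict:
    table = _load_table(config, preprocessed_csv)
    selection = SelectionResult.from_json(selection_json)
    restricted = table.subset_features(selection.selected_features)
    cv_cfg = CVConfig.from_dict(config.cv.to_dict())
    cv_cfg.seed = stage_seed(config.seed, "cv")
    specs = config.model_specs()
    report = cross_validate(restricted, specs, cv_cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "cv_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    (outdir / "models").mkdir(exist_ok=True)
    arts = ["cv_report.json"]
    for spec in specs:
        fit_final(restricted, spec).save(outdir / "models" / f"{spec.kind}.joblib")
        arts.append(f"models/{spec.kind}.joblib")
    if config.weight_scheme == "uniform":
        weights = VoteWeights.uniform([s.kind for s in specs])
    else:
        weights = VoteWeights.from_accuracies(report.accuracies())
    with open(outdir / "weights.json", "w") as fh:
        json.dump(weights.weights, fh, indent=2, sort_keys=True)
    arts.append("weights.json")
    from sklearn.metrics import roc_curve

    scored = report.oof_fold_ids >= 0
    for kind in report.model_kinds:
        fpr, tpr, thr = roc_curve(report.oof_true[scored], report.oof_probabilities[kind][scored])
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
            outdir / f"roc_{kind}.csv", index=False
        )
        arts.append(f"roc_{kind}.csv")
    return {"stage": "train", "artifacts": arts, "best_model": report.best_model}


def stage_vote(config: PipelineConfig, outdir: Path, models_dir, preprocessor_json, holdout_csv) -> dict:
    models_dir = Path(models_dir)
    model_files = sorted(models_dir.glob("*.joblib"))
    if not model_files:
        raise FileNotFoundError(
            f"no trained models in {models_dir}; run the train stage first "
            f"(expected models/<KIND>.joblib)"
        )
    models = [FittedModel.load(p) for p in model_files]
    with open(Path(models_dir).parent / "weights.json") as fh:
        weights = VoteWeights(weights=json.load(fh))
    pp = Preprocessor.load(preprocessor_json)
    holdout = _load_table(config, holdout_csv)
    transformed = pp.transform(holdout)
    restricted = transformed.subset_features(models[0].feature_names)
    preds = validate_holdout(models, weights, restricted)
    outdir.mkdir(parents=True, exist_ok=True)
    write_prediction_report(preds, outdir / "predictions.csv")
    summary = {"n": len(preds)}
    if preds.y_true is not None:
        summary["hard_correct"] = count_correct(preds, "hard")
        summary["soft_correct"] = count_correct(preds, "soft")
    with open(outdir / "voting_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return {"stage": "vote", "artifacts": ["predictions.csv", "voting_summary.json"], **summary}


def run_all(config: PipelineConfig, outdir) -> Path:
    """Execute simulate/ingest -> preprocess -> select -> train -> vote and
    write every artifact plus a provenance manifest into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logs: list[dict] = []

    def _run(fn, *args):
        t0 = time.perf_counter()
        entry = fn(*args)
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        logs.append(entry)
        return entry

    if config.synthetic is not None:
        _run(stage_simulate, config, outdir)
        cohort_csv = outdir / "cohort.csv"
    else:
        cohort_csv = Path(config.input_path)
    _run(stage_preprocess, config, outdir, cohort_csv)
    _run(stage_select, config, outdir, outdir / "preprocessed.csv")
    _run(stage_train, config, outdir, outdir / "preprocessed.csv", outdir / "selection.json")

    if config.holdout_path is not None:
        holdout_csv = Path(config.holdout_path)
    elif config.synthetic is not None and config.holdout_n > 0:
        holdout_csv = outdir / "holdout.csv"
    else:
        holdout_csv = cohort_csv  # resubstitution report when no holdout given
    _run(stage_vote, config, outdir, outdir / "models", outdir / "preprocessor.json", holdout_csv)

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "version": __version__,
        "stages": logs,
        "artifacts": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
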
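"""End-to-end orchestration: simulate/ingest → descriptors → filter → build →
select → cross-validate → holdout validation, with artifacts on disk.

Every run is driven by a :class:`RunConfig` (loadable from YAML) and a seed;
a rerun with the same config reproduces every report byte-for-byte.  The
two classifiers ranking best by pooled CV accuracy (ties broken by AUC) are
retrained on the full training table and applied to the independent
validation cohort, after excluding any miRNA already seen in training.
"""

from __future__ import annotations

import dataclasses
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classifiers import CLASSIFIER_NAMES, ClassifierSpec, TrainedModel, fit_model
from .core import FeatureTable
from .dataset_builder import (
    P_MAX_DEFAULT,
    SCORE_MIN_DEFAULT,
    build_table,
    exclude_overlap,
    filter_annotations,
    vocabulary_of,
)
from .evaluation import EvalReport, cross_validate, validate_holdout
from .feature_select import best_first_select, selection_report
from .formats_io import (
    apply_labels,
    read_annotations,
    read_fasta,
    read_labels,
    write_annotations,
    write_arff,
    write_fasta,
    write_json,
    write_labels,
    write_table_csv,
)
from .synthetic_cohort import SyntheticConfig, generate_cohort, generate_validation

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int
    outdir: str = "mirclass_out"
    k: int = 10
    score_min: float = SCORE_MIN_DEFAULT
    p_max: float = P_MAX_DEFAULT
    stale_limit: int = 5
    max_features: int | None = None
    classifiers: list[str] = field(default_factory=lambda: list(CLASSIFIER_NAMES))
    # either synthetic generation …
    synthetic: dict = field(default_factory=dict)
    n_validation: int = 18
    # … or explicit input paths
    paths: dict = field(default_factory=dict)
    validation_paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "seed" not in data:
            raise ValueError(f"{path}: config must set a seed")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": dataclasses.asdict(model.spec),
        "feature_names": model.feature_names,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format")
    return payload["model"]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapped

    return deco


@_stage("ingest")
def _load_cohort(cfg: RunConfig, outdir: Path):
    if cfg.paths:
        for key in ("fasta", "targets", "pathways", "labels"):
            if key not in cfg.paths:
                raise ValueError(f"config paths missing {key!r}")
        records = read_fasta(cfg.paths["fasta"])
        records = apply_labels(records, read_labels(cfg.paths["labels"]))
        ann = read_annotations(cfg.paths["targets"], cfg.paths["pathways"])
        return records, ann
    syn = SyntheticConfig(**{**cfg.synthetic, "seed": cfg.seed})
    records, ann = generate_cohort(syn)
    write_fasta(records, outdir / "cohort.fasta")
    write_labels(records, outdir / "labels.tsv")
    write_annotations(ann, outdir / "targets.tsv", outdir / "pathways.tsv")
    return records, ann


@_stage("ingest-validation")
def _load_validation(cfg: RunConfig, training_ids: set[str], outdir: Path):
    if cfg.validation_paths:
        records = read_fasta(cfg.validation_paths["fasta"])
        records = apply_labels(records, read_labels(cfg.validation_paths["labels"]))
        ann = read_annotations(
            cfg.validation_paths["targets"], cfg.validation_paths["pathways"]
        )
    else:
        syn = SyntheticConfig(**{**cfg.synthetic, "seed": cfg.seed})
        records, ann = generate_validation(syn, training_ids, n=cfg.n_validation)
        write_fasta(records, outdir / "validation.fasta")
        write_labels(records, outdir / "validation_labels.tsv")
        write_annotations(
            ann, outdir / "validation_targets.tsv", outdir / "validation_pathways.tsv"
        )
    records = exclude_overlap(records, training_ids)
    return records, ann


@_stage("build")
def _build(records, ann, cfg: RunConfig, vocab=None) -> FeatureTable:
    filtered = filter_annotations(ann, score_min=cfg.score_min, p_max=cfg.p_max)
    return build_table(records, filtered, vocab=vocab)


def run_pipeline(cfg: RunConfig) -> dict[str, EvalReport]:
    """Execute the full pipeline; returns CV and holdout reports by name.

    Artifacts written under ``cfg.outdir``: the (possibly simulated) cohort
    and annotation tables, the training table as ARFF and CSV, the selection
    report, one JSON evaluation report per classifier, holdout reports for
    the two best learners, and a manifest sufficient to reproduce the run.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "reports").mkdir(exist_ok=True)
    (outdir / "holdout").mkdir(exist_ok=True)

    records, ann = _load_cohort(cfg, outdir)
    train_table = _build(records, ann, cfg)
    write_arff(train_table, outdir / "train.arff")
    write_table_csv(train_table, outdir / "train.csv")

    try:
        subset = best_first_select(
            train_table, stale_limit=cfg.stale_limit, max_features=cfg.max_features
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"stage 'select': {exc}") from exc
    write_json(selection_report(subset, train_table), outdir / "selection.json")
    selected = (
        train_table.select_columns(subset.feature_indices)
        if subset.feature_indices
        else train_table
    )

    reports: dict[str, EvalReport] = {}
    for i, name in enumerate(cfg.classifiers):
        spec = ClassifierSpec(name, seed=cfg.seed * 100 + i)
        try:
            rep = cross_validate(spec, selected, k=cfg.k, seed=cfg.seed)
        except Exception as exc:
            raise PipelineError(f"stage 'evaluate:{name}': {exc}") from exc
        reports[name] = rep
        write_json(rep.to_dict(), outdir / "reports" / f"{name}.json")

    # top-2 by CV accuracy, ties by AUC
    ranked = sorted(
        cfg.classifiers,
        key=lambda n: (reports[n].accuracy_pct, reports[n].auc),
        reverse=True,
    )
    top2 = ranked[:2]

    training_ids = {r.mirna_id for r in records}
    val_records, val_ann = _load_validation(cfg, training_ids, outdir)
    val_table = _build(val_records, val_ann, cfg, vocab=vocabulary_of(train_table))
    if subset.feature_indices:
        val_table = val_table.select_columns(subset.feature_indices)
    write_arff(val_table, outdir / "validation.arff")

    holdout: dict[str, EvalReport] = {}
    for i, name in enumerate(top2):
        spec = ClassifierSpec(name, seed=cfg.seed * 100 + cfg.classifiers.index(name))
        try:
            model = fit_model(spec, selected)
            save_model(model, outdir / f"model_{name}.pkl")
            rep = validate_holdout(model, val_table)
        except Exception as exc:
            raise PipelineError(f"stage 'validate:{name}': {exc}") from exc
        holdout[name] = rep
        write_json(rep.to_dict(), outdir / "holdout" / f"{name}.json")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "n_training_rows": train_table.n_rows,
        "n_features_built": train_table.n_features,
        "selected_features": subset.feature_names(train_table),
        "selection_merit": subset.merit,
        "cv_ranking": ranked,
        "holdout_models": top2,
    }
    write_json(manifest, outdir / "manifest.json")

    return {**{f"cv:{n}": r for n, r in reports.items()},
            **{f"holdout:{n}": r for n, r in holdout.items()}}
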
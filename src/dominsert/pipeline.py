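"""Declarative end-to-end runs: simulate -> curate -> split -> encode ->
train -> evaluate.

`run_pipeline` is the library's orchestration surface. It takes a nested
config (dict, or a path to a JSON/YAML file), validates it against the
known stage schema before anything executes, runs the requested stages in
dependency order, and leaves every output directory self-describing: the
verbatim config, its hash and the seed are written alongside the
artifacts. Stages started without their upstream products present fail
with an error naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import corpus as corpus_mod
from . import evaluation, model, splits, synthetic
from .corpus import InsertionRecord, make_label_vector, read_cluster_map
from .encoding import FixtureEmbedder, OneHotProvider, encode_with_provider

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class MissingArtifactError(RuntimeError):
    pass


STAGE_ORDER = ("simulate", "curate", "split", "encode", "train", "evaluate")

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "outdir", "log_level", "stages"} | set(STAGE_ORDER),
    "simulate": {
        "n_proteins",
        "length_range",
        "motif",
        "insert_length_range",
        "n_parent_superfamilies",
        "n_insert_superfamilies",
        "decoy_fraction",
        "n_duplicate_clusters",
        "zipf_exponent",
    },
    "curate": {"fasta", "annotations", "cluster_map", "max_len", "gap_slack"},
    "split": {"strategy", "test_fraction", "train_fraction"},
    "encode": {"encoder", "dimension", "k"},
    "train": {
        "learning_rate",
        "total_steps",
        "checkpoint_every",
        "hidden_dim",
        "window_radius",
    },
    "evaluate": {"window_radius"},
}


def _validate(config: dict[str, Any]) -> None:
    unknown = set(config) - _SCHEMA[""]
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    for stage in STAGE_ORDER:
        section = config.get(stage, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {stage!r} must be a mapping")
        bad = set(section) - _SCHEMA[stage]
        if bad:
            raise ConfigError(
                f"unknown keys in section {stage!r}: {sorted(bad)}"
            )
    stages = config.get("stages", list(STAGE_ORDER))
    bad_stages = set(stages) - set(STAGE_ORDER)
    if bad_stages:
        raise ConfigError(f"unknown stages requested: {sorted(bad_stages)}")


def _load_config(source: dict[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        if str(source).endswith((".yaml", ".yml")):
            import yaml

            return yaml.safe_load(text)
        return json.loads(text)
    return dict(source)


@dataclass
class PipelineResult:
    outdir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    report: dict[str, Any] = field(default_factory=dict)


def run_pipeline(config: dict[str, Any] | str | Path) -> PipelineResult:
    """Execute the requested stages and return artifact paths plus a report.

    The default stage list is the full synthetic rehearsal; a real-data run
    would request ``curate`` onward and point the ``curate`` section at its
    own FASTA/annotation/cluster files.
    """
    config = _load_config(config)
    _validate(config)
    outdir = Path(config.get("outdir", "dominsert_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    logging.basicConfig(
        level=getattr(logging, str(config.get("log_level", "INFO")).upper())
    )

    config_text = json.dumps(config, indent=1, sort_keys=True, default=str)
    config_hash = hashlib.sha256(config_text.encode()).hexdigest()[:16]
    (outdir / "run_config.json").write_text(config_text)
    (outdir / "run_manifest.json").write_text(
        json.dumps({"seed": seed, "config_sha256_16": config_hash}, indent=1)
    )

    stages = list(config.get("stages", list(STAGE_ORDER)))
    result = PipelineResult(outdir)
    state: dict[str, Any] = {}

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        logger.info("stage %s starting (seed %d)", stage, seed)
        _RUNNERS[stage](config, seed, outdir, state, result)
        logger.info("stage %s done", stage)
    return result


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _run_simulate(config, seed, outdir, state, result) -> None:
    section = config.get("simulate", {})
    kwargs = dict(section)
    for key in ("length_range", "insert_length_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    fixture = synthetic.FixtureConfig(seed=seed, **kwargs)
    corpus = synthetic.generate_synthetic_corpus(fixture)
    paths = corpus.write(outdir / "simulate")
    state["synthetic"] = corpus
    result.artifacts.update({f"simulate/{k}": v for k, v in paths.items()})
    result.report["n_simulated_proteins"] = len(corpus.sequences)


def _simulated_paths(config, outdir) -> dict[str, Path]:
    section = config.get("curate", {})
    base = outdir / "simulate"
    paths = {
        "fasta": Path(section["fasta"]) if "fasta" in section else base / "proteome.fasta",
        "annotations": (
            Path(section["annotations"])
            if "annotations" in section
            else base / "annotations.tsv"
        ),
        "cluster_map": (
            Path(section["cluster_map"])
            if "cluster_map" in section
            else base / "clusters.tsv"
        ),
    }
    for name, p in paths.items():
        if not p.exists():
            raise MissingArtifactError(
                f"curate needs {name} at {p}; run the simulate stage or "
                "point the curate section at existing files"
            )
    return paths


def _run_curate(config, seed, outdir, state, result) -> None:
    section = config.get("curate", {})
    paths = _simulated_paths(config, outdir)
    records = corpus_mod.curate(
        paths["annotations"],
        paths["fasta"],
        cluster_map=read_cluster_map(paths["cluster_map"]),
        max_len=section.get("max_len", 2048),
        gap_slack=section.get("gap_slack", 0),
    )
    stage_dir = outdir / "curate"
    stage_dir.mkdir(exist_ok=True)
    corpus_mod.write_records_fasta(records, stage_dir / "parent_only.fasta")
    corpus_mod.write_records_tsv(records, stage_dir / "records.tsv")
    corpus_mod.corpus_statistics(records).write(stage_dir / "statistics")
    state["records"] = records
    result.artifacts["curate/records"] = stage_dir / "records.tsv"
    result.artifacts["curate/fasta"] = stage_dir / "parent_only.fasta"
    result.report["n_curated_records"] = len(records)


def _require_records(outdir, state) -> list[InsertionRecord]:
    if "records" in state:
        return state["records"]
    tsv = outdir / "curate" / "records.tsv"
    fasta = outdir / "curate" / "parent_only.fasta"
    if not tsv.exists():
        raise MissingArtifactError(
            f"no curated records at {tsv}; run the curate stage first"
        )
    return corpus_mod.read_records_tsv(tsv, fasta)


def _run_split(config, seed, outdir, state, result) -> None:
    section = config.get("split", {})
    records = _require_records(outdir, state)
    test_set = splits.build_common_test_set(
        records, fraction=section.get("test_fraction", 0.10), seed=seed
    )
    strategy = section.get("strategy", "combination")
    if strategy == "random":
        assignment = splits.split_random(records, test_set, seed=seed)
    elif strategy == "combination":
        assignment = splits.split_by_combination(records, test_set, seed=seed)
    elif strategy == "single":
        assignment = splits.split_single_representative(
            records,
            test_set,
            train_fraction=section.get("train_fraction", 0.79),
            seed=seed,
        )
    else:
        raise ConfigError(f"unknown split strategy {strategy!r}")
    stage_dir = outdir / "split"
    stage_dir.mkdir(exist_ok=True)
    assignment.write(stage_dir / f"{strategy}.tsv")
    state["split"] = assignment
    result.artifacts["split/assignment"] = stage_dir / f"{strategy}.tsv"
    result.report["split_sizes"] = {
        part: len(recs) for part, recs in assignment.parts.items()
    }


def _make_provider(config, seed):
    section = config.get("encode", {})
    encoder = section.get("encoder", "fixture")
    if encoder == "onehot":
        return OneHotProvider()
    if encoder == "fixture":
        return FixtureEmbedder(
            dimension=section.get("dimension", 64),
            seed=seed,
            k=section.get("k", 5),
        )
    raise ConfigError(f"unknown encoder {encoder!r}")


def _run_encode(config, seed, outdir, state, result) -> None:
    provider = _make_provider(config, seed)
    if "split" not in state:
        raise MissingArtifactError(
            "encode needs the split stage's in-memory assignment; "
            "run split in the same pipeline invocation"
        )
    cache_dir = outdir / "encode"
    encoded: dict[str, Any] = {}
    for part, records in state["split"].parts.items():
        for rec in records:
            encoded[rec.record_id] = encode_with_provider(
                rec.parent_only_sequence,
                provider,
                accession=rec.record_id,
                cache_dir=cache_dir,
            )
    state["provider"] = provider
    state["encodings"] = encoded
    result.artifacts["encode/cache"] = cache_dir
    result.report["encoder_id"] = provider.encoder_id


def _examples_for(records, state, window_radius: int):
    out = []
    for rec in records:
        enc = state["encodings"][rec.record_id]
        out.append(
            model.TrainingExample(
                rec.record_id,
                enc.matrix,
                make_label_vector(rec, window_radius),
                enc.encoder_id,
            )
        )
    return out


def _run_train(config, seed, outdir, state, result) -> None:
    section = config.get("train", {})
    if "encodings" not in state or "split" not in state:
        raise MissingArtifactError(
            "train needs split + encode stages in the same invocation"
        )
    cfg = model.TrainConfig(
        learning_rate=section.get("learning_rate", 1e-5),
        total_steps=section.get("total_steps", 1500),
        checkpoint_every=section.get("checkpoint_every", 100),
        seed=seed,
        hidden_dim=section.get("hidden_dim", 512),
        window_radius=section.get("window_radius", 1),
    )
    assignment = state["split"]
    train_ex = _examples_for(assignment.train, state, cfg.window_radius)
    val_ex = _examples_for(assignment.validation, state, cfg.window_radius)
    checkpoints, log = model.train(
        train_ex, cfg, val_ex, checkpoint_dir=outdir / "train"
    )
    state["checkpoints"] = checkpoints
    state["train_config"] = cfg
    result.artifacts["train/checkpoints"] = outdir / "train"
    final = checkpoints[-1]
    result.report["final_step"] = final.step
    result.report["final_train_loss"] = final.train_loss
    if final.validation_auroc is not None:
        result.report["final_validation_auroc"] = final.validation_auroc


def _run_evaluate(config, seed, outdir, state, result) -> None:
    section = config.get("evaluate", {})
    radius = section.get("window_radius", 1)
    if "checkpoints" not in state:
        raise MissingArtifactError(
            "evaluate needs the train stage in the same invocation"
        )
    final = state["checkpoints"][-1]
    assignment = state["split"]
    aurocs = []
    for rec in assignment.test:
        enc = state["encodings"][rec.record_id]
        trace = evaluation.predict_from_encoding(
            final.params, enc, final.checkpoint_id
        )
        lab = make_label_vector(rec, radius)
        labels = evaluation.BenchmarkLabelSet(
            tuple(
                evaluation.POS if v == corpus_mod.LABEL_POSITIVE else evaluation.NEG
                for v in lab.labels
            ),
            "junction_truth",
        )
        aurocs.append(evaluation.auroc(trace, labels))
    stage_dir = outdir / "evaluate"
    stage_dir.mkdir(exist_ok=True)
    report = {
        "n_test_records": len(aurocs),
        "mean_test_auroc": float(np.mean(aurocs)) if aurocs else None,
        "checkpoint": final.checkpoint_id,
    }
    (stage_dir / "report.json").write_text(json.dumps(report, indent=1))
    result.artifacts["evaluate/report"] = stage_dir / "report.json"
    result.report.update(report)


_RUNNERS = {
    "simulate": _run_simulate,
    "curate": _run_curate,
    "split": _run_split,
    "encode": _run_encode,
    "train": _run_train,
    "evaluate": _run_evaluate,
}
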
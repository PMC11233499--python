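"""End-to-end orchestration: configuration, seeds, staged artifacts.

A run is reproducible from its :class:`RunConfig` plus the code version:
one global seed fans out to per-stage seeds through named
``numpy.random.SeedSequence`` derivations, every stage writes its artifacts
together with a manifest (config hash, input hashes, seed, timing), and a
re-run with the same config reuses artifacts whose manifest still matches.

Stages: generate -> ingest -> train -> evaluate -> refine -> surrogate.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import assay_data, evaluation, model, synthetic, transfer
from .assay_data import LabelMatrix
from .tasks import TaskSpec, default_registry, load_registry, registry_hash

logger = logging.getLogger(__name__)

STAGES = ("generate", "ingest", "train", "evaluate", "refine", "surrogate")

_STAGE_SEED_KEY = {name: i + 1 for i, name in enumerate(STAGES)}


class MissingDependencyError(RuntimeError):
    """A stage needs an artifact that an earlier stage has not produced."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Named deterministic per-stage seed derivation (< 2^31)."""
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, _STAGE_SEED_KEY[stage]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "runs/default"
    seed: int = 0
    n_total: int = 5000
    tasks_file: Optional[str] = None          # None -> standard 6-task registry
    cutoff_date: str = "2021-12-31"
    refine_cutoff_date: str = "2022-12-31"
    noise_sd: float = 0.3
    hidden_width: int = 64
    message_passing_depth: int = 2
    ffn_layers: int = 2
    ensemble_size: int = 2
    max_epochs: int = 25
    patience: int = 5
    fine_tune_strategy: str = "modality_specific"
    n_boot: int = 1000
    min_stratum_size: int = 5
    surrogate_n: int = 2000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _registry(config: RunConfig) -> list[TaskSpec]:
    if config.tasks_file is None:
        return synthetic.standard_task_registry()
    return load_registry(config.tasks_file)


def _write_manifest(out: Path, stage: str, config: RunConfig,
                    inputs: Sequence[Path], outputs: Sequence[Path],
                    elapsed: float) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": stage_seed(config.seed, stage),
        "inputs": {p.name: _file_hash(p) for p in inputs if p.exists()},
        "outputs": {p.name: _file_hash(p) for p in outputs if p.exists()},
        "elapsed_seconds": round(elapsed, 3),
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_cached(out: Path, stage: str, config: RunConfig, outputs: Sequence[Path]) -> bool:
    mpath = out / f"manifest_{stage}.json"
    if not mpath.exists():
        return False
    manifest = json.loads(mpath.read_text())
    if manifest.get("config_hash") != config.config_hash():
        return False
    return all(p.exists() for p in outputs)


def _require(out: Path, stage_needed: str, *paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise MissingDependencyError(
                f"missing artifact {p.name}; run the '{stage_needed}' stage first"
            )


@dataclass
class _RunState:
    """Lazily loaded artifacts shared between stages of one invocation."""

    molecules: Optional[list] = None
    matrix: Optional[LabelMatrix] = None


def _load_molecules(out: Path) -> list:
    return assay_data.read_compounds_csv(out / "compounds.csv")


def _load_matrix(out: Path, registry: Sequence[TaskSpec]) -> LabelMatrix:
    records = assay_data.read_measurements_csv(out / "measurements.csv")
    matrix, _ = assay_data.ingest_measurements(records, registry)
    return matrix


def _model_config(config: RunConfig, registry: Sequence[TaskSpec], stage: str) -> model.ModelConfig:
    return model.ModelConfig(
        n_tasks=len(registry),
        message_passing_depth=config.message_passing_depth,
        hidden_width=config.hidden_width,
        ffn_layers=config.ffn_layers,
        ensemble_size=config.ensemble_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=stage_seed(config.seed, stage),
    )


def run_pipeline(config: RunConfig, stages: Sequence[str]) -> dict[str, str]:
    """Execute the requested stages; returns {stage: status}.

    Stage dependencies are checked explicitly and a missing upstream
    artifact raises :class:`MissingDependencyError` naming the stage to run
    first. Completed stages with an up-to-date manifest are reused.
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    registry = _registry(config)
    cutoff = _dt.date.fromisoformat(config.cutoff_date)
    refine_cutoff = _dt.date.fromisoformat(config.refine_cutoff_date)
    status: dict[str, str] = {}

    ordered = [s for s in STAGES if s in set(stages)]
    for stage in ordered:
        t0 = time.perf_counter()
        if stage == "generate":
            outputs = [out / "compounds.csv", out / "measurements.csv",
                       out / "ground_truth.json"]
            if _stage_cached(out, stage, config, outputs):
                status[stage] = "cached"
                continue
            gen_cfg = replace(
                synthetic.standard_study_config(stage_seed(config.seed, stage),
                                                n_total=config.n_total),
                noise_sd=config.noise_sd,
            )
            study = synthetic.generate_study(gen_cfg, registry)
            assay_data.write_compounds_csv(study.molecules, outputs[0])
            assay_data.write_measurements_csv(study.records, outputs[1])
            truth_blob = {
                "compound_ids": study.truth.compound_ids,
                "task_ids": study.truth.task_ids,
                "values": study.truth.values.tolist(),
                "descriptor_means": study.truth.descriptor_means.tolist(),
                "descriptor_sds": study.truth.descriptor_sds.tolist(),
            }
            outputs[2].write_text(json.dumps(truth_blob, sort_keys=True))
            _write_manifest(out, stage, config, [], outputs, time.perf_counter() - t0)
            status[stage] = "done"

        elif stage == "ingest":
            _require(out, "generate", out / "compounds.csv", out / "measurements.csv")
            outputs = [out / "label_matrix.npz"]
            if _stage_cached(out, stage, config, outputs):
                status[stage] = "cached"
                continue
            matrix = _load_matrix(out, registry)
            np.savez(outputs[0], values=matrix.values, mask=matrix.mask,
                     compound_ids=np.array(matrix.compound_ids),
                     task_ids=np.array(matrix.task_ids))
            _write_manifest(out, stage, config,
                            [out / "compounds.csv", out / "measurements.csv"],
                            outputs, time.perf_counter() - t0)
            status[stage] = "done"

        elif stage == "train":
            _require(out, "generate", out / "compounds.csv", out / "measurements.csv")
            outputs = [out / "model.npz"]
            if _stage_cached(out, stage, config, outputs):
                status[stage] = "cached"
                continue
            molecules = _load_molecules(out)
            matrix = _load_matrix(out, registry)
            split, _ = assay_data.temporal_split(molecules, cutoff)
            train_matrix = matrix.subset(
                [c for c in split.train_ids if c in matrix.row_index()])
            ensemble = model.train(train_matrix, molecules,
                                   _model_config(config, registry, "train"))
            ensemble.registry_fingerprint = registry_hash(registry)
            model.save_checkpoint(ensemble, outputs[0])
            _write_manifest(out, stage, config,
                            [out / "measurements.csv"], outputs,
                            time.perf_counter() - t0)
            status[stage] = "done"

        elif stage == "evaluate":
            _require(out, "train", out / "model.npz")
            reports = out / "reports"
            outputs = [reports / "evaluation.csv", reports / "evaluation.json"]
            if _stage_cached(out, stage, config, outputs):
                status[stage] = "cached"
                continue
            molecules = _load_molecules(out)
            matrix = _load_matrix(out, registry)
            ensemble = model.load_checkpoint(out / "model.npz")
            split, counts = assay_data.temporal_split(molecules, cutoff)
            report = evaluation.evaluate(
                ensemble, molecules, matrix, split, registry,
                min_stratum_size=config.min_stratum_size,
                n_boot=config.n_boot, seed=stage_seed(config.seed, stage),
            )
            evaluation.write_report(report, reports)
            counts.to_csv(reports / "split_counts.csv", index=False)
            _write_manifest(out, stage, config, [out / "model.npz"], outputs,
                            time.perf_counter() - t0)
            status[stage] = "done"

        elif stage == "refine":
            _require(out, "train", out / "model.npz")
            reports = out / "reports"
            outputs = [out / "model_fine_tuned.npz", out / "model_retrained.npz",
                       reports / "refinement.csv"]
            if _stage_cached(out, stage, config, outputs):
                status[stage] = "cached"
                continue
            molecules = _load_molecules(out)
            matrix = _load_matrix(out, registry)
            original = model.load_checkpoint(out / "model.npz")
            ft_cfg = transfer.FineTuneConfig(
                strategy=config.fine_tune_strategy,
                seed=stage_seed(config.seed, stage),
            )
            subset = transfer.select_refinement_subset(
                molecules, ft_cfg, cutoff, refine_cutoff)
            subset_ids = [m.compound_id for m in subset if m.compound_id in matrix.row_index()]
            tuned = transfer.fine_tune(original, subset, matrix.subset(subset_ids), ft_cfg)
            retrain_mols = [m for m in molecules if m.registration_date <= refine_cutoff]
            retrain_ids = [m.compound_id for m in retrain_mols
                           if m.compound_id in matrix.row_index()]
            retrained = transfer.retrain(
                matrix.subset(retrain_ids), retrain_mols,
                _model_config(config, registry, "refine"))
            model.save_checkpoint(tuned, outputs[0])
            model.save_checkpoint(retrained, outputs[1])
            # Side-by-side report on post-refine-cutoff heterobifunctionals.
            test_mols = [m for m in molecules
                         if m.modality == "heterobifunctional"
                         and m.registration_date > refine_cutoff]
            rows = []
            by_id = matrix.row_index()
            test_ids = [m.compound_id for m in test_mols if m.compound_id in by_id]
            if test_ids:
                test_matrix = matrix.subset(test_ids)
                mols_by_id = {m.compound_id: m for m in molecules}
                test_list = [mols_by_id[c] for c in test_matrix.compound_ids]
                for label, ens in (("original", original), ("retrained", retrained),
                                   (f"fine_tuned_{config.fine_tune_strategy}", tuned)):
                    preds = model.predict(ens, test_list)
                    for j, tid in enumerate(test_matrix.task_ids):
                        m_col = test_matrix.mask[:, j]
                        if m_col.sum() < config.min_stratum_size:
                            continue
                        y = test_matrix.values[m_col, j]
                        p = preds.values[m_col, preds.task_ids.index(tid)]
                        rows.append({"model": label, "task_id": tid,
                                     "n": int(m_col.sum()),
                                     "mae": float(np.abs(y - p).mean())})
            reports.mkdir(parents=True, exist_ok=True)
            import pandas as pd

            pd.DataFrame(rows).to_csv(outputs[2], index=False)
            _write_manifest(out, stage, config, [out / "model.npz"], outputs,
                            time.perf_counter() - t0)
            status[stage] = "done"

        elif stage == "surrogate":
            _require(out, "train", out / "model.npz")
            reports = out / "reports"
            outputs = [out / "surrogate.csv", out / "model_student.npz",
                       reports / "distillation.csv"]
            if _stage_cached(out, stage, config, outputs):
                status[stage] = "cached"
                continue
            teacher = model.load_checkpoint(out / "model.npz")
            seed = stage_seed(config.seed, stage)
            gen_cfg = replace(
                synthetic.standard_study_config(seed, n_total=config.surrogate_n),
                seed=seed + 1,
            )
            library = synthetic.generate_library(gen_cfg)
            n_holdout = max(50, config.surrogate_n // 10)
            train_structs = [m.structure for m in library[:-n_holdout]]
            holdout = library[-n_holdout:]
            surrogate = transfer.build_surrogate(train_structs, teacher)
            surrogate.frame.to_csv(outputs[0], index=False)
            student = transfer.distill(
                surrogate, _model_config(config, registry, "surrogate"))
            model.save_checkpoint(student, outputs[1])
            teacher_preds = model.predict(teacher, holdout)
            student_preds = model.predict(student, holdout)
            report = transfer.correlate(teacher_preds, student_preds)
            reports.mkdir(parents=True, exist_ok=True)
            report.to_frame().to_csv(outputs[2], index=False)
            _write_manifest(out, stage, config, [out / "model.npz"], outputs,
                            time.perf_counter() - t0)
            status[stage] = "done"

    return status
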
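"""Canned synthetic-study experiments.

These functions bundle the standard study conditions into runnable
experiments: train-and-evaluate on the temporal split, the analytic
noise-floor comparison, the heterobifunctional down-weighting /
fine-tuning experiment, and teacher-student distillation. The analysis
drivers, the test suite, and the acceptance script all run the same code
paths from here.

Problem sizes: the standard study uses 5000 compounds and 6 tasks with
noise sd 0.3; the fine-tuning experiment down-weights heterobifunctionals
to 2% of the library; distillation uses 20000 surrogate structures with a
2000-structure held-out set. Model capacity for these studies (width 64,
depth 2, one ensemble member, up to 45 epochs) is chosen so a full study
trains in about a minute on one CPU core while sitting within a factor
~1.2 of the analytic noise floor.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import evaluation, model, transfer
from .assay_data import LabelMatrix, ingest_measurements, temporal_split
from .chemistry import Molecule
from .model import ModelConfig, TrainedEnsemble
from .synthetic import (STANDARD_CUTOFF, STANDARD_SPARSITY, GeneratorConfig,
                        SyntheticStudy, generate_library, generate_study,
                        standard_study_config, standard_task_registry)
from .tasks import TaskSpec

#: Refinement cutoff of the fine-tuning experiment: the original model is
#: trained on pre-2022 compounds, fine-tuned on heterobifunctionals through
#: mid-2022, and tested on later heterobifunctionals.
REFINE_CUTOFF = _dt.date(2022, 6, 30)

ANALYTIC_MAE_FLOOR = 0.3 * float(np.sqrt(2.0 / np.pi))  # E|N(0, 0.3)|


def standard_model_config(n_tasks: int, seed: int) -> ModelConfig:
    """Study-scale architecture (see module docstring for sizing)."""
    return ModelConfig(
        n_tasks=n_tasks, hidden_width=64, message_passing_depth=2,
        ffn_layers=2, ensemble_size=1, max_epochs=45, patience=6, seed=seed,
    )


@dataclass
class StudyRun:
    """A generated study with its ingested matrix and temporal split."""

    study: SyntheticStudy
    matrix: LabelMatrix
    train_matrix: LabelMatrix
    test_matrix: LabelMatrix
    molecules_by_id: dict[str, Molecule]

    @property
    def registry(self) -> list[TaskSpec]:
        return self.study.registry

    def test_molecules(self) -> list[Molecule]:
        return [self.molecules_by_id[c] for c in self.test_matrix.compound_ids]


def run_standard_study(seed: int, n_total: int = 5000,
                       cfg: GeneratorConfig | None = None) -> StudyRun:
    registry = standard_task_registry()
    cfg = cfg or standard_study_config(seed, n_total=n_total)
    study = generate_study(cfg, registry)
    matrix, _ = ingest_measurements(study.records, registry)
    split, _ = temporal_split(study.molecules, STANDARD_CUTOFF)
    train_matrix = matrix.subset([c for c in split.train_ids if c in matrix.row_index()])
    test_matrix = matrix.subset([c for c in split.test_ids if c in matrix.row_index()])
    return StudyRun(
        study=study, matrix=matrix, train_matrix=train_matrix,
        test_matrix=test_matrix,
        molecules_by_id={m.compound_id: m for m in study.molecules},
    )


def train_standard_model(run: StudyRun, seed: int) -> TrainedEnsemble:
    cfg = standard_model_config(len(run.matrix.task_ids), seed)
    return model.train(run.train_matrix, run.study.molecules, cfg)


def oracle_holdout_mae(run: StudyRun) -> tuple[float, int]:
    """Pooled MAE of the truth-returning oracle on observed test labels.

    With Gaussian noise of sd sigma on model scale this estimates
    sigma*sqrt(2/pi), slightly shrunk by replicate aggregation.
    """
    truth = run.study.truth
    rows = {c: i for i, c in enumerate(truth.compound_ids)}
    errs = []
    for j, tid in enumerate(run.test_matrix.task_ids):
        jt = truth.task_ids.index(tid)
        for i, cid in enumerate(run.test_matrix.compound_ids):
            if run.test_matrix.mask[i, j]:
                errs.append(abs(run.test_matrix.values[i, j]
                                - truth.values[rows[cid], jt]))
    return float(np.mean(errs)), len(errs)


def model_vs_baseline(run: StudyRun, ensemble: TrainedEnsemble
                      ) -> tuple[dict[str, dict[str, float]], float, float]:
    """Per-task model/baseline test MAE plus pooled model and baseline MAE."""
    preds = model.predict(ensemble, run.test_molecules())
    baseline = evaluation.baseline_predict(run.train_matrix,
                                           run.test_matrix.compound_ids)
    per_task: dict[str, dict[str, float]] = {}
    err_sum = n_sum = base_sum = 0.0
    for j, tid in enumerate(run.test_matrix.task_ids):
        mask = run.test_matrix.mask[:, j]
        y = run.test_matrix.values[mask, j]
        p = preds.values[mask, preds.task_ids.index(tid)]
        b = baseline.values[mask, baseline.task_ids.index(tid)]
        per_task[tid] = {
            "n": int(mask.sum()),
            "model_mae": float(np.abs(y - p).mean()),
            "baseline_mae": float(np.abs(y - b).mean()),
        }
        err_sum += np.abs(y - p).sum()
        base_sum += np.abs(y - b).sum()
        n_sum += mask.sum()
    return per_task, float(err_sum / n_sum), float(base_sum / n_sum)


# ---------------------------------------------------------------------------
# Fine-tuning experiment (heterobifunctionals down-weighted to 2%)
# ---------------------------------------------------------------------------

def downweighted_study_config(seed: int, n_total: int = 4000,
                              het_fraction: float = 0.02) -> GeneratorConfig:
    n_het = int(round(n_total * het_fraction))
    rest = n_total - n_het
    return GeneratorConfig(
        n_per_modality={"heterobifunctional": n_het, "glue": rest // 2,
                        "other": rest - rest // 2},
        noise_sd=0.3, sparsity=dict(STANDARD_SPARSITY),
        replicate_rate=0.1, qualifier_rate=0.05, seed=seed,
    )


def fine_tuning_experiment(seed: int, n_total: int = 4000
                           ) -> dict[str, dict[str, float]]:
    """Train on a heterobifunctional-poor library, fine-tune on
    heterobifunctionals (strategy 2), compare MAE on later
    heterobifunctionals. Returns per-task original/tuned MAE."""
    registry = standard_task_registry()
    cfg = downweighted_study_config(seed, n_total=n_total)
    study = generate_study(cfg, registry)
    matrix, _ = ingest_measurements(study.records, registry)
    split, _ = temporal_split(study.molecules, STANDARD_CUTOFF)
    train_matrix = matrix.subset([c for c in split.train_ids if c in matrix.row_index()])
    mcfg = replace(standard_model_config(len(registry), seed + 100),
                   max_epochs=35)
    original = model.train(train_matrix, study.molecules, mcfg)

    ft_cfg = transfer.FineTuneConfig(strategy="modality_specific",
                                     seed=seed + 200, max_epochs=20, patience=5)
    subset = transfer.select_refinement_subset(study.molecules, ft_cfg,
                                               STANDARD_CUTOFF, REFINE_CUTOFF)
    subset_ids = [m.compound_id for m in subset if m.compound_id in matrix.row_index()]
    tuned = transfer.fine_tune(original, subset, matrix.subset(subset_ids), ft_cfg)

    test_mols = [m for m in study.molecules
                 if m.modality == "heterobifunctional"
                 and m.registration_date > REFINE_CUTOFF
                 and m.compound_id in matrix.row_index()]
    test_matrix = matrix.subset([m.compound_id for m in test_mols])
    by_id = {m.compound_id: m for m in study.molecules}
    test_list = [by_id[c] for c in test_matrix.compound_ids]
    p_orig = model.predict(original, test_list)
    p_tuned = model.predict(tuned, test_list)
    out: dict[str, dict[str, float]] = {}
    for j, tid in enumerate(test_matrix.task_ids):
        mask = test_matrix.mask[:, j]
        if mask.sum() < 5:
            continue
        y = test_matrix.values[mask, j]
        out[tid] = {
            "n": int(mask.sum()),
            "original_mae": float(np.abs(y - p_orig.values[mask, p_orig.task_ids.index(tid)]).mean()),
            "fine_tuned_mae": float(np.abs(y - p_tuned.values[mask, p_tuned.task_ids.index(tid)]).mean()),
        }
    return out


def fine_tuning_improvement_count(seeds: Sequence[int]) -> tuple[int, int, dict]:
    """Tasks improved (mean MAE over seeds) by strategy-2 fine-tuning."""
    pooled: dict[str, dict[str, list[float]]] = {}
    for seed in seeds:
        for tid, row in fine_tuning_experiment(seed).items():
            entry = pooled.setdefault(tid, {"original": [], "fine_tuned": []})
            entry["original"].append(row["original_mae"])
            entry["fine_tuned"].append(row["fine_tuned_mae"])
    summary = {
        tid: {"original_mae": float(np.mean(v["original"])),
              "fine_tuned_mae": float(np.mean(v["fine_tuned"]))}
        for tid, v in pooled.items()
    }
    improved = sum(1 for v in summary.values()
                   if v["fine_tuned_mae"] < v["original_mae"])
    return improved, len(summary), summary


# ---------------------------------------------------------------------------
# Distillation experiment
# ---------------------------------------------------------------------------

def surrogate_structure_sets(seed: int, n_train: int = 20000,
                             n_holdout: int = 2000
                             ) -> tuple[list[str], list[Molecule]]:
    """Unique synthetic structures for distillation: pseudo-label training
    set and a disjoint held-out set. Oversamples the generator and slices
    unique canonical structures."""
    needed = n_train + n_holdout
    oversample = int(2.4 * needed)
    library = generate_library(standard_study_config(seed, n_total=oversample))
    seen: set[str] = set()
    unique: list[Molecule] = []
    for m in library:
        if m.structure not in seen:
            seen.add(m.structure)
            unique.append(m)
    if len(unique) < needed:
        raise RuntimeError(
            f"generator yielded only {len(unique)} unique structures; "
            f"{needed} required")
    train = [m.structure for m in unique[:n_train]]
    holdout = unique[n_train:needed]
    return train, holdout


def distillation_experiment(teacher: TrainedEnsemble, seed: int,
                            n_train: int = 20000, n_holdout: int = 2000
                            ) -> transfer.CorrelationReport:
    """Distill a student from dense teacher pseudo-labels and report
    per-task teacher-student fidelity on held-out structures."""
    train_structs, holdout = surrogate_structure_sets(seed, n_train, n_holdout)
    surrogate = transfer.build_surrogate(train_structs, teacher)
    student_cfg = replace(teacher.config, seed=seed + 1,
                          max_epochs=25, patience=4)
    student = transfer.distill(surrogate, student_cfg)
    teacher_preds = model.predict(teacher, holdout)
    student_preds = model.predict(student, holdout)
    return transfer.correlate(teacher_preds, student_preds)
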
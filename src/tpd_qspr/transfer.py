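"""Model refinement and surrogate distillation.

Refinement adapts a trained global ensemble to the heterobifunctional
domain: *fine-tuning* continues training from the original weights on a
refinement subset (strategy 1: all compounds from the year after the
training cutoff; strategy 2: heterobifunctional degraders registered before
a later cutoff), with a gentler learning-rate schedule; *retraining* rebuilds
the ensemble from scratch on all data through the new cutoff.

Distillation trains a student ensemble of identical architecture on a
teacher's dense predictions over a structure library (pseudo-labels), and
reports per-task Pearson/Spearman fidelity between student and teacher.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay_data import LabelMatrix
from .chemistry import Molecule, StructureParseError, standardize_structure
from .model import ModelConfig, PredictionTable, TrainedEnsemble, predict, train
from .tasks import TaskSpec

logger = logging.getLogger(__name__)

STRATEGIES = ("all_new_data", "modality_specific")


@dataclass(frozen=True)
class FineTuneConfig:
    """Refinement settings; the strategy only selects the subset."""

    strategy: str
    lr_scale: float = 0.1       # lr_max lowered 10x relative to the original run
    warmup_epochs: int = 1
    max_epochs: int = 15
    patience: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")


def select_refinement_subset(
    molecules: Sequence[Molecule],
    cfg: FineTuneConfig,
    train_cutoff: _dt.date,
    refine_cutoff: _dt.date,
) -> list[Molecule]:
    """Pick the refinement compounds for a strategy.

    ``all_new_data``: every compound registered after the original training
    cutoff and up to the refinement cutoff. ``modality_specific``:
    heterobifunctional degraders registered up to the refinement cutoff
    (including pre-cutoff training compounds).
    """
    if cfg.strategy == "all_new_data":
        subset = [m for m in molecules
                  if train_cutoff < m.registration_date <= refine_cutoff]
    else:
        subset = [m for m in molecules
                  if m.modality == "heterobifunctional"
                  and m.registration_date <= refine_cutoff]
    if not subset:
        raise ValueError(f"strategy {cfg.strategy!r} selected an empty refinement subset")
    return subset


def fine_tune(
    original: TrainedEnsemble,
    molecules: Sequence[Molecule],
    matrix: LabelMatrix,
    cfg: FineTuneConfig,
) -> TrainedEnsemble:
    """Continue training each member from the original weights.

    All layers stay trainable; the label standardization of the original
    model is reused so member weights remain compatible. The original
    ensemble is left unmodified. A fresh scaffold-based validation split is
    drawn within the refinement subset for early stopping.
    """
    if list(matrix.task_ids) != list(original.task_ids):
        raise ValueError("refinement matrix tasks do not match the original ensemble")
    if not molecules:
        raise ValueError("empty refinement data")
    base_cfg = original.config
    tune_cfg = replace(
        base_cfg,
        lr_init=base_cfg.lr_init * cfg.lr_scale,
        lr_max=base_cfg.lr_max * cfg.lr_scale,
        lr_final=base_cfg.lr_final * cfg.lr_scale,
        warmup_epochs=cfg.warmup_epochs,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        seed=cfg.seed,
    )
    if cfg.max_epochs == 0:
        tuned = original.copy()
        tuned.audit = {"run_label": f"fine_tuned_{cfg.strategy}", "epochs": 0}
        return tuned
    return train(
        matrix,
        molecules,
        tune_cfg,
        initial_members=original.members,
        standardization=(original.label_means, original.label_sds),
        run_label=f"fine_tuned_{cfg.strategy}",
    )


def retrain(
    matrix: LabelMatrix,
    molecules: Sequence[Molecule],
    cfg: ModelConfig,
) -> TrainedEnsemble:
    """Train from fresh initialization on all data through the new cutoff."""
    return train(matrix, molecules, cfg, run_label="retrained")


# ---------------------------------------------------------------------------
# Surrogate data set and distillation
# ---------------------------------------------------------------------------

@dataclass
class SurrogateDataset:
    """Standardized unique structures with dense teacher pseudo-labels."""

    frame: pd.DataFrame          # canonical_smiles + one column per task
    task_ids: list[str]
    rejects: list[str]

    def __post_init__(self) -> None:
        if self.frame["canonical_smiles"].duplicated().any():
            raise ValueError("surrogate rows must be unique canonical structures")

    @property
    def n(self) -> int:
        return len(self.frame)


def build_surrogate(
    structures: Sequence[str],
    teacher: TrainedEnsemble,
    rejects_path: str | Path | None = None,
) -> SurrogateDataset:
    """Standardize, deduplicate, and densely annotate structures with
    teacher predictions. Unparsable entries go to the rejects list and the
    run continues."""
    canonical: list[str] = []
    rejects: list[str] = []
    seen = set()
    for raw in structures:
        try:
            smi = standardize_structure(raw)
        except StructureParseError:
            rejects.append(raw)
            continue
        if smi not in seen:
            seen.add(smi)
            canonical.append(smi)
    if rejects and rejects_path is not None:
        Path(rejects_path).write_text("\n".join(rejects) + "\n")
    molecules = [
        Molecule(compound_id=f"SUR-{i:06d}", structure=s, modality="other",
                 registration_date=_dt.date(2000, 1, 1))
        for i, s in enumerate(canonical)
    ]
    preds = predict(teacher, molecules)
    frame = pd.DataFrame(preds.values, columns=preds.task_ids)
    frame.insert(0, "canonical_smiles", canonical)
    return SurrogateDataset(frame=frame, task_ids=list(preds.task_ids), rejects=rejects)


def distill(
    surrogate: SurrogateDataset,
    cfg: ModelConfig,
) -> TrainedEnsemble:
    """Train a student on the dense pseudo-labels (mask all-true)."""
    if surrogate.n == 0:
        raise ValueError("empty surrogate data set")
    molecules = [
        Molecule(compound_id=f"SUR-{i:06d}", structure=s, modality="other",
                 registration_date=_dt.date(2000, 1, 1))
        for i, s in enumerate(surrogate.frame["canonical_smiles"])
    ]
    values = surrogate.frame[surrogate.task_ids].to_numpy(dtype=float)
    matrix = LabelMatrix(
        compound_ids=[m.compound_id for m in molecules],
        task_ids=list(surrogate.task_ids),
        values=values,
        mask=np.ones_like(values, dtype=bool),
    )
    # LabelMatrix orders rows by compound_id; SUR ids are already sorted.
    return train(matrix, molecules, cfg, run_label="distilled")


@dataclass(frozen=True)
class TaskCorrelation:
    task_id: str
    pearson_r: Optional[float]
    spearman_rho: Optional[float]
    n: int
    flag: str = ""


@dataclass
class CorrelationReport:
    per_task: list[TaskCorrelation]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.per_task])

    def min_pearson(self) -> float:
        values = [t.pearson_r for t in self.per_task if t.pearson_r is not None]
        if not values:
            raise ValueError("no defined correlations")
        return min(values)


def correlate(
    teacher_preds: PredictionTable,
    student_preds: PredictionTable,
) -> CorrelationReport:
    """Per-task Pearson r and Spearman rho between two prediction tables."""
    if teacher_preds.compound_ids != student_preds.compound_ids:
        raise ValueError("prediction tables must cover the same compounds in order")
    out = []
    for tid in teacher_preds.task_ids:
        t = teacher_preds.column(tid)
        s = student_preds.column(tid)
        n = len(t)
        if n < 3:
            raise ValueError(f"task {tid}: need at least 3 pairs")
        if np.std(t) < 1e-12 or np.std(s) < 1e-12:
            out.append(TaskCorrelation(tid, None, None, n, flag="constant_vector"))
            continue
        r = float(stats.pearsonr(t, s).statistic)
        rho = float(stats.spearmanr(t, s).statistic)
        out.append(TaskCorrelation(tid, r, rho, n))
    return CorrelationReport(per_task=out)
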
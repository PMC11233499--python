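"""Measurement ingestion: qualifier policy, replicate aggregation,
transforms, sparse label-matrix construction, and temporal splitting.

Raw assay records arrive as (compound, task, value, qualifier, date) rows.
Qualified readouts ('<'/'>') are censored values and are discarded --
mandatorily for permeability, plasma protein binding, LogP, and LogD tasks,
and by default (configurable) everywhere else. Replicates are aggregated
with the geometric mean on the raw scale (equivalently the arithmetic mean
on the model scale, which is also what identity-transform tasks such as
LogD use). Aggregated values are transformed to model scale and assembled
into a sparse compound x task matrix with an observation mask.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chemistry import Molecule
from .tasks import TaskSpec

logger = logging.getLogger(__name__)

QUALIFIERS = ("exact", "less_than", "greater_than")

_QUALIFIER_SYMBOLS = {"exact": "=", "less_than": "<", "greater_than": ">"}
_SYMBOL_QUALIFIERS = {v: k for k, v in _QUALIFIER_SYMBOLS.items()}

#: Task families for which the qualifier discard is mandatory: permeability
#: (model group), PPB-type F_u tasks, LogP, and LogD.
_MANDATORY_DISCARD_QUANTITIES = {"F_u", "LogP", "LogD"}


@dataclass(frozen=True)
class AssayMeasurement:
    """One raw replicate measurement on the raw assay scale."""

    compound_id: str
    task_id: str
    raw_value: float
    qualifier: str = "exact"
    measured_date: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier!r}")


@dataclass(frozen=True)
class QualifierPolicy:
    """How censored ('<'/'>') readouts are handled.

    ``discard_everywhere`` extends the mandatory discard (permeability, PPB,
    LogP, LogD) to every task; disabling it keeps qualified records for
    clearance and CYP tasks.
    """

    discard_everywhere: bool = True


def qualifier_discard_applies(spec: TaskSpec, policy: QualifierPolicy) -> bool:
    if spec.model_group == "permeability" or spec.raw_quantity in _MANDATORY_DISCARD_QUANTITIES:
        return True
    return policy.discard_everywhere


def apply_qualifier_policy(
    records: Sequence[AssayMeasurement],
    spec: TaskSpec,
    policy: QualifierPolicy | None = None,
) -> tuple[list[AssayMeasurement], int]:
    """Filter qualified records for one task; returns (kept, n_discarded)."""
    policy = policy or QualifierPolicy()
    for r in records:
        if r.task_id != spec.task_id:
            raise ValueError(f"record for {r.task_id!r} passed to task {spec.task_id!r}")
    if not qualifier_discard_applies(spec, policy):
        return list(records), 0
    kept = [r for r in records if r.qualifier == "exact"]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("task %s: discarded %d qualified records", spec.task_id, n_dropped)
    return kept, n_dropped


def apply_dynamic_range(
    records: Sequence[AssayMeasurement], spec: TaskSpec
) -> tuple[list[AssayMeasurement], int]:
    """Drop values outside the task's configured assay dynamic range."""
    if spec.dynamic_range is None:
        return list(records), 0
    lo, hi = spec.dynamic_range
    kept = [r for r in records if lo <= r.raw_value <= hi]
    return kept, len(records) - len(kept)


def aggregate_replicates(
    records: Sequence[AssayMeasurement], spec: TaskSpec
) -> dict[str, float]:
    """Aggregate replicates per compound on the raw scale.

    Geometric mean for log-family tasks (arithmetic mean of the model-scale
    values, back-transformed), arithmetic mean for identity-transform tasks.
    Singletons pass through unchanged.
    """
    by_compound: dict[str, list[float]] = {}
    for r in records:
        if spec.transform != "identity" and r.raw_value <= 0:
            raise ValueError(
                f"nonpositive value {r.raw_value} for {r.compound_id}/{r.task_id} "
                "on a geometric-mean task"
            )
        by_compound.setdefault(r.compound_id, []).append(r.raw_value)
    out: dict[str, float] = {}
    for cid, values in by_compound.items():
        if len(values) == 1:
            out[cid] = float(values[0])
        else:
            model_vals = [spec.to_model_scale(v) for v in values]
            out[cid] = spec.from_model_scale(float(np.mean(model_vals)))
    return out


def to_model_scale(raw: float, spec: TaskSpec) -> float:
    """Transform a raw assay value to model scale (delegates to the task)."""
    return spec.to_model_scale(raw)


def from_model_scale(value: float, spec: TaskSpec) -> float:
    return spec.from_model_scale(value)


@dataclass
class LabelMatrix:
    """Sparse compound x task matrix of model-scale labels with a mask."""

    compound_ids: list[str]
    task_ids: list[str]
    values: np.ndarray  # (n_compounds, n_tasks) float64, 0 where unobserved
    mask: np.ndarray    # (n_compounds, n_tasks) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.compound_ids), len(self.task_ids)):
            raise ValueError("matrix shape inconsistent with id lists")

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def density(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def row_index(self) -> dict[str, int]:
        return {cid: i for i, cid in enumerate(self.compound_ids)}

    def subset(self, compound_ids: Sequence[str]) -> "LabelMatrix":
        idx = self.row_index()
        rows = [idx[c] for c in compound_ids]
        return LabelMatrix(
            compound_ids=list(compound_ids),
            task_ids=list(self.task_ids),
            values=self.values[rows].copy(),
            mask=self.mask[rows].copy(),
        )


def build_label_matrix(
    aggregated: Mapping[tuple[str, str], float],
    registry: Sequence[TaskSpec],
    compounds: Sequence[str] | None = None,
) -> LabelMatrix:
    """Assemble model-scale labels into a sparse matrix.

    ``aggregated`` maps (compound_id, task_id) to the aggregated RAW value.
    Rows are ordered by compound_id, columns by task_id (deterministic).
    """
    spec_by_id = {s.task_id: s for s in registry}
    for (_, tid) in aggregated:
        if tid not in spec_by_id:
            raise ValueError(f"task {tid!r} not in registry")
    if compounds is None:
        compounds = sorted({cid for cid, _ in aggregated})
    else:
        compounds = sorted(compounds)
    task_ids = sorted(spec_by_id)
    row = {c: i for i, c in enumerate(compounds)}
    col = {t: j for j, t in enumerate(task_ids)}
    values = np.zeros((len(compounds), len(task_ids)), dtype=np.float64)
    mask = np.zeros_like(values, dtype=bool)
    for (cid, tid), raw in aggregated.items():
        i, j = row[cid], col[tid]
        if mask[i, j]:
            raise ValueError(f"duplicate entry for ({cid}, {tid}) after aggregation")
        values[i, j] = spec_by_id[tid].to_model_scale(raw)
        mask[i, j] = True
    return LabelMatrix(compound_ids=list(compounds), task_ids=task_ids,
                       values=values, mask=mask)


def ingest_measurements(
    records: Sequence[AssayMeasurement],
    registry: Sequence[TaskSpec],
    compounds: Sequence[str] | None = None,
    policy: QualifierPolicy | None = None,
) -> tuple[LabelMatrix, dict[str, dict[str, int]]]:
    """Full ingestion: qualifier policy -> dynamic range -> aggregation ->
    label matrix. Returns the matrix and a per-task audit of dropped counts.
    """
    policy = policy or QualifierPolicy()
    by_task: dict[str, list[AssayMeasurement]] = {}
    for r in records:
        by_task.setdefault(r.task_id, []).append(r)
    aggregated: dict[tuple[str, str], float] = {}
    audit: dict[str, dict[str, int]] = {}
    for spec in registry:
        task_records = by_task.get(spec.task_id, [])
        kept, n_qual = apply_qualifier_policy(task_records, spec, policy)
        kept, n_range = apply_dynamic_range(kept, spec)
        for cid, value in aggregate_replicates(kept, spec).items():
            aggregated[(cid, spec.task_id)] = value
        audit[spec.task_id] = {
            "n_records": len(task_records),
            "n_qualifier_discarded": n_qual,
            "n_out_of_range": n_range,
        }
    matrix = build_label_matrix(aggregated, registry, compounds)
    return matrix, audit


@dataclass(frozen=True)
class DataSplit:
    """Temporal train/test partition at a registration-date cutoff."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    cutoff_date: _dt.date

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def temporal_split(
    molecules: Sequence[Molecule], cutoff_date: _dt.date
) -> tuple[DataSplit, pd.DataFrame]:
    """Split compounds at a registration-date cutoff.

    Train: registration_date <= cutoff; test: registration_date > cutoff.
    Also returns per-modality train/test counts.
    """
    train, test = [], []
    for m in molecules:
        if m.registration_date is None:
            raise ValueError(f"{m.compound_id}: missing registration date")
        (train if m.registration_date <= cutoff_date else test).append(m)
    counts = []
    for modality in ("glue", "heterobifunctional", "other"):
        counts.append({
            "modality": modality,
            "n_train": sum(1 for m in train if m.modality == modality),
            "n_test": sum(1 for m in test if m.modality == modality),
        })
    split = DataSplit(
        train_ids=tuple(m.compound_id for m in train),
        test_ids=tuple(m.compound_id for m in test),
        cutoff_date=cutoff_date,
    )
    return split, pd.DataFrame(counts)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_compounds_csv(molecules: Sequence[Molecule], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "compound_id": [m.compound_id for m in molecules],
            "smiles": [m.structure for m in molecules],
            "modality": [m.modality for m in molecules],
            "registration_date": [m.registration_date.isoformat() for m in molecules],
        }
    )
    df.to_csv(path, index=False)


def read_compounds_csv(path: str | Path) -> list[Molecule]:
    df = pd.read_csv(path, dtype={"compound_id": str})
    return [
        Molecule(
            compound_id=row.compound_id,
            structure=row.smiles,
            modality=row.modality,
            registration_date=_dt.date.fromisoformat(row.registration_date),
        )
        for row in df.itertuples()
    ]


def write_measurements_csv(records: Sequence[AssayMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "task_id": [r.task_id for r in records],
            "raw_value": [r.raw_value for r in records],
            "qualifier": [_QUALIFIER_SYMBOLS[r.qualifier] for r in records],
            "measured_date": [
                "" if r.measured_date is None else r.measured_date.isoformat()
                for r in records
            ],
        }
    )
    df.to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> list[AssayMeasurement]:
    df = pd.read_csv(path, dtype={"compound_id": str}, keep_default_na=False)
    out = []
    for row in df.itertuples():
        date = row.measured_date or None
        out.append(
            AssayMeasurement(
                compound_id=row.compound_id,
                task_id=row.task_id,
                raw_value=float(row.raw_value),
                qualifier=_SYMBOL_QUALIFIERS[row.qualifier],
                measured_date=None if date is None else _dt.date.fromisoformat(date),
            )
        )
    return out
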
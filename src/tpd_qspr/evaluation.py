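"""Temporal-split, modality-stratified benchmarking.

For every evaluated task and modality stratum (glues, heterobifunctionals,
other, and the pooled 'all') with at least five labeled test compounds, the
report carries the regression MAE, the three-class decision metrics, a
bootstrap distribution of the MAE (pairs resampled with replacement,
n=1000), and the MAE of a constant baseline predicting the training-set
mean. Smaller strata are flagged and skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assay_data import DataSplit, LabelMatrix
from .chemistry import Molecule
from .model import PredictionTable, TrainedEnsemble, predict
from .risk import (ClassificationReport, RegressionReport, categorize_many,
                   classification_metrics, mae)
from .tasks import TaskSpec

STRATA = ("glue", "heterobifunctional", "other", "all")


def baseline_predict(
    train_matrix: LabelMatrix,
    test_compound_ids: Sequence[str],
) -> PredictionTable:
    """Constant per-task prediction: the mean of the training labels."""
    n_tasks = len(train_matrix.task_ids)
    means = np.zeros(n_tasks)
    for j in range(n_tasks):
        obs = train_matrix.values[:, j][train_matrix.mask[:, j]]
        if obs.size == 0:
            raise ValueError(f"no training labels for task {train_matrix.task_ids[j]!r}")
        means[j] = obs.mean()
    values = np.tile(means, (len(test_compound_ids), 1))
    return PredictionTable(
        compound_ids=list(test_compound_ids),
        task_ids=list(train_matrix.task_ids),
        values=values,
        spread=np.zeros_like(values),
    )


@dataclass(frozen=True)
class BootstrapResult:
    """MAE distribution over bootstrap resamples of (pred, label) pairs."""

    n_boot: int
    mae_samples: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if len(self.mae_samples) != self.n_boot:
            raise ValueError("sample count differs from n_boot")

    def quantiles(self) -> dict[str, float]:
        q1, med, q3 = np.percentile(self.mae_samples, [25, 50, 75])
        iqr = q3 - q1
        return {
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_low": float(q1 - 1.5 * iqr),
            "whisker_high": float(q3 + 1.5 * iqr),
        }


def bootstrap_mae(
    preds: Sequence[float],
    labels: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Resample prediction/label pairs with replacement and record each MAE."""
    p = np.asarray(preds, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("paired 1-D preds and labels required")
    n = p.size
    if n < 2:
        raise ValueError("bootstrap needs at least 2 pairs")
    rng = np.random.default_rng(seed)
    abs_err = np.abs(y - p)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = abs_err[idx].mean(axis=1)
    return BootstrapResult(n_boot=n_boot, mae_samples=samples, seed=seed)


@dataclass
class StratumResult:
    task_id: str
    stratum: str
    regression: RegressionReport
    classification: Optional[ClassificationReport]
    bootstrap: BootstrapResult
    baseline_mae: float

    def to_row(self) -> dict:
        row = {
            "task_id": self.task_id,
            "stratum": self.stratum,
            "n": self.regression.n,
            "mae": self.regression.mae,
            "baseline_mae": self.baseline_mae,
        }
        row.update({f"bootstrap_{k}": v for k, v in self.bootstrap.quantiles().items()})
        if self.classification is not None:
            row.update({
                "error_low_pct": self.classification.error_low,
                "error_high_pct": self.classification.error_high,
                "precision_low_pct": self.classification.precision_low,
                "precision_high_pct": self.classification.precision_high,
                "inconclusive_pct": self.classification.inconclusive_pct,
            })
        return row


@dataclass
class ModalityReport:
    """All stratum results plus an audit of skipped (too small) strata."""

    results: list[StratumResult]
    skipped: list[dict]
    min_stratum_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])

    def get(self, task_id: str, stratum: str) -> Optional[StratumResult]:
        for r in self.results:
            if r.task_id == task_id and r.stratum == stratum:
                return r
        return None

    def to_json_dict(self) -> dict:
        return {
            "min_stratum_size": self.min_stratum_size,
            "results": [r.to_row() for r in self.results],
            "skipped": self.skipped,
        }


def evaluate_predictions(
    predictions: PredictionTable,
    test_matrix: LabelMatrix,
    train_matrix: LabelMatrix,
    registry: Sequence[TaskSpec],
    modalities: Mapping[str, str],
    min_stratum_size: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
) -> ModalityReport:
    """Score a prediction table against test labels, stratified by modality."""
    spec_by_id = {s.task_id: s for s in registry}
    baseline = baseline_predict(train_matrix, predictions.compound_ids)
    pred_rows = {c: i for i, c in enumerate(predictions.compound_ids)}
    results: list[StratumResult] = []
    skipped: list[dict] = []
    boot_seed = seed
    for j, tid in enumerate(test_matrix.task_ids):
        spec = spec_by_id.get(tid)
        if spec is None or not spec.evaluated:
            continue
        jp = predictions.task_ids.index(tid)
        for stratum in STRATA:
            rows = [
                i for i, cid in enumerate(test_matrix.compound_ids)
                if test_matrix.mask[i, j]
                and cid in pred_rows
                and (stratum == "all" or modalities.get(cid) == stratum)
            ]
            if len(rows) < min_stratum_size:
                skipped.append({"task_id": tid, "stratum": stratum, "n": len(rows)})
                continue
            cids = [test_matrix.compound_ids[i] for i in rows]
            y = test_matrix.values[rows, j]
            p = np.asarray([predictions.values[pred_rows[c], jp] for c in cids])
            b = np.asarray([baseline.values[pred_rows[c], jp] for c in cids])
            classification = None
            if spec.has_risk_rules:
                classification = classification_metrics(
                    categorize_many(p, spec), categorize_many(y, spec)
                )
            boot_seed += 1
            results.append(StratumResult(
                task_id=tid,
                stratum=stratum,
                regression=mae(p, y),
                classification=classification,
                bootstrap=bootstrap_mae(p, y, n_boot=n_boot, seed=boot_seed),
                baseline_mae=mae(b, y).mae,
            ))
    return ModalityReport(results=results, skipped=skipped,
                          min_stratum_size=min_stratum_size)


def evaluate(
    ensemble: TrainedEnsemble,
    molecules: Sequence[Molecule],
    matrix: LabelMatrix,
    split: DataSplit,
    registry: Sequence[TaskSpec],
    min_stratum_size: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
) -> ModalityReport:
    """Temporal-split evaluation of a trained ensemble.

    Trains nothing: predicts the post-cutoff compounds and scores them
    against their labels, with the pre-cutoff labels defining the baseline.
    """
    by_id = {m.compound_id: m for m in molecules}
    test_ids = [c for c in split.test_ids if c in by_id]
    train_matrix = matrix.subset([c for c in split.train_ids if c in matrix.row_index()])
    test_matrix = matrix.subset([c for c in test_ids if c in matrix.row_index()])
    preds = predict(ensemble, [by_id[c] for c in test_matrix.compound_ids])
    modalities = {m.compound_id: m.modality for m in molecules}
    return evaluate_predictions(
        preds, test_matrix, train_matrix, registry, modalities,
        min_stratum_size=min_stratum_size, n_boot=n_boot, seed=seed,
    )


def write_report(report: ModalityReport, out_dir: str | Path, stem: str = "evaluation") -> None:
    """CSV + JSON report mirroring the per-task, per-modality table layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out / f"{stem}.csv", index=False)
    (out / f"{stem}.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True)
    )
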
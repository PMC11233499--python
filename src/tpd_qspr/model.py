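"""Training and prediction for the multi-task GNN ensemble.

An ensemble member is a directed-bond message-passing encoder plus
feed-forward head trained on the sparse label matrix with a masked loss.
Members share the architecture and task ordering and differ by seeded
initialization and minibatch order. Early stopping monitors the masked loss
on a 10% validation set held out by whole Bemis-Murcko scaffold groups, so
no framework appears on both sides. Labels are standardized per task (zero
mean, unit variance on the training portion) before the loss and the
standardization is inverted at prediction time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import nn
from .assay_data import LabelMatrix
from .chemistry import Molecule, scaffold_key
from .graphs import BatchedGraph, FeaturizerConfig, MolecularGraph, batch_graphs, featurize
from .tasks import TaskSpec, registry_hash

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings for one ensemble."""

    n_tasks: int
    message_passing_depth: int = 3
    hidden_width: int = 300
    ffn_layers: int = 2
    ensemble_size: int = 5
    batch_size: int = 50
    lr_init: float = 1e-4
    lr_max: float = 1e-3
    lr_final: float = 1e-4
    warmup_epochs: int = 2
    max_epochs: int = 30
    patience: int = 6
    # early stopping is armed only after this many epochs, so a validation
    # plateau during learning-rate warm-up cannot abort training
    min_epochs: int = 12
    validation_fraction: float = 0.10
    seed: int = 0
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)

    def __post_init__(self) -> None:
        if self.lr_init > self.lr_max:
            raise ValueError("lr_init must be <= lr_max")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


@dataclass
class TrainedEnsemble:
    """Trained members plus everything needed to reproduce predictions."""

    members: list[nn.Params]
    config: ModelConfig
    task_ids: list[str]
    label_means: np.ndarray
    label_sds: np.ndarray
    registry_fingerprint: str
    audit: dict

    def copy(self) -> "TrainedEnsemble":
        return TrainedEnsemble(
            members=[nn.clone_params(p) for p in self.members],
            config=self.config,
            task_ids=list(self.task_ids),
            label_means=self.label_means.copy(),
            label_sds=self.label_sds.copy(),
            registry_fingerprint=self.registry_fingerprint,
            audit=json.loads(json.dumps(self.audit)),
        )


@dataclass
class PredictionTable:
    """Ensemble-mean model-scale predictions and member spread."""

    compound_ids: list[str]
    task_ids: list[str]
    values: np.ndarray  # (n, n_tasks) ensemble mean, model scale
    spread: np.ndarray  # (n, n_tasks) member standard deviation

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.task_ids)
        df.insert(0, "compound_id", self.compound_ids)
        return df

    def column(self, task_id: str) -> np.ndarray:
        return self.values[:, self.task_ids.index(task_id)]


def scaffold_validation_split(
    molecules: Sequence[Molecule],
    fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Hold out ~``fraction`` of molecules by whole scaffold groups.

    Returns (train_idx, val_idx); no scaffold key occurs on both sides.
    """
    groups: dict[str, list[int]] = {}
    for i, mol in enumerate(molecules):
        groups.setdefault(scaffold_key(mol), []).append(i)
    keys = sorted(groups)
    order = rng.permutation(len(keys))
    target = fraction * len(molecules)
    val_idx: list[int] = []
    for k in order:
        if len(val_idx) >= target:
            break
        val_idx.extend(groups[keys[k]])
    val = np.asarray(sorted(val_idx), dtype=np.int64)
    train = np.asarray(sorted(set(range(len(molecules))) - set(val_idx)), dtype=np.int64)
    if len(train) == 0 or len(val) == 0:
        raise ValueError("scaffold split produced an empty side; too few scaffolds")
    return train, val


def _align_molecules(matrix: LabelMatrix, molecules: Sequence[Molecule]) -> list[Molecule]:
    by_id = {m.compound_id: m for m in molecules}
    missing = [c for c in matrix.compound_ids if c not in by_id]
    if missing:
        raise ValueError(f"molecules missing for {len(missing)} matrix rows, e.g. {missing[:3]}")
    return [by_id[c] for c in matrix.compound_ids]


def featurize_library(
    molecules: Sequence[Molecule], config: FeaturizerConfig
) -> list[MolecularGraph]:
    return [featurize(m, config) for m in molecules]


def _standardize(matrix: LabelMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = np.zeros(len(matrix.task_ids))
    sds = np.ones(len(matrix.task_ids))
    for j, tid in enumerate(matrix.task_ids):
        obs = matrix.values[rows, j][matrix.mask[rows, j]]
        if obs.size == 0:
            logger.warning("task %s has no labeled training cell; identity scaling", tid)
            continue
        means[j] = obs.mean()
        sd = obs.std()
        sds[j] = sd if sd > 1e-12 else 1.0
    return means, sds


def train(
    matrix: LabelMatrix,
    molecules: Sequence[Molecule],
    cfg: ModelConfig,
    graphs: Optional[Sequence[MolecularGraph]] = None,
    initial_members: Optional[Sequence[nn.Params]] = None,
    standardization: Optional[tuple[np.ndarray, np.ndarray]] = None,
    run_label: str = "train",
) -> TrainedEnsemble:
    """Train an ensemble on a sparse label matrix.

    ``graphs`` may carry pre-featurized molecules (aligned to
    ``matrix.compound_ids``); ``initial_members`` warm-starts each member
    from existing weights, and ``standardization`` fixes the per-task label
    means/sds instead of refitting them (both used by fine-tuning, where
    warm-started weights must keep seeing labels on their original scale).
    """
    if cfg.n_tasks != len(matrix.task_ids):
        raise ValueError(f"config expects {cfg.n_tasks} tasks, matrix has {len(matrix.task_ids)}")
    labeled = matrix.mask.any(axis=1)
    if int(labeled.sum()) < 20:
        raise ValueError(f"too little data: {int(labeled.sum())} labeled compounds (< 20)")
    mols = _align_molecules(matrix, molecules)
    if graphs is None:
        graphs = featurize_library(mols, cfg.featurizer)
    graphs = list(graphs)

    root = np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 101])
    split_rng = np.random.default_rng(root.spawn(1)[0])
    train_idx, val_idx = scaffold_validation_split(mols, cfg.validation_fraction, split_rng)
    if standardization is not None:
        means, sds = np.asarray(standardization[0]), np.asarray(standardization[1])
    else:
        means, sds = _standardize(matrix, train_idx)
    y = (matrix.values - means) / sds
    mask = matrix.mask

    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / cfg.batch_size)))
    schedule = nn.LRSchedule(
        lr_init=cfg.lr_init, lr_max=cfg.lr_max, lr_final=cfg.lr_final,
        warmup_steps=cfg.warmup_epochs * steps_per_epoch,
        total_steps=cfg.max_epochs * steps_per_epoch,
    )

    val_batch = batch_graphs([graphs[i] for i in val_idx])
    y_val, m_val = y[val_idx], mask[val_idx]

    members: list[nn.Params] = []
    member_audits = []
    atom_dim, bond_dim = cfg.featurizer.atom_dim, cfg.featurizer.bond_dim
    for member in range(cfg.ensemble_size):
        mrng = np.random.default_rng(root.spawn(member + 2)[0])
        if initial_members is not None:
            params = nn.clone_params(initial_members[member])
        else:
            params = nn.init_params(atom_dim, bond_dim, cfg.hidden_width,
                                    cfg.ffn_layers, cfg.n_tasks, mrng)
        opt = nn.Adam(params)
        best_val = np.inf
        best_params = nn.clone_params(params)
        best_epoch = -1
        epochs_log = []
        step = 0
        for epoch in range(cfg.max_epochs):
            order = mrng.permutation(len(train_idx))
            epoch_loss, n_batches = 0.0, 0
            for s in range(0, len(order), cfg.batch_size):
                rows = train_idx[order[s:s + cfg.batch_size]]
                batch = batch_graphs([graphs[i] for i in rows])
                preds, cache = nn.forward(batch, params, cfg.message_passing_depth,
                                          want_cache=True)
                loss = nn.masked_mt_loss(preds, y[rows], mask[rows])
                dout = nn.masked_mt_loss_grad(preds, y[rows], mask[rows])
                grads = nn.backward(dout, params, cache)
                opt.step(params, grads, schedule.lr_at(step))
                step += 1
                epoch_loss += loss
                n_batches += 1
            val_preds, _ = nn.forward(val_batch, params, cfg.message_passing_depth)
            val_loss = nn.masked_mt_loss(val_preds, y_val, m_val)
            epochs_log.append({
                "epoch": epoch, "train_loss": epoch_loss / max(1, n_batches),
                "val_loss": val_loss, "lr": schedule.lr_at(step - 1),
            })
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = nn.clone_params(params)
                best_epoch = epoch
            elif epoch + 1 >= cfg.min_epochs and epoch - best_epoch >= cfg.patience:
                break
        members.append(best_params)
        member_audits.append({
            "member": member, "best_epoch": best_epoch, "best_val_loss": best_val,
            "epochs": epochs_log,
        })
        logger.info("%s member %d: best epoch %d val loss %.4f",
                    run_label, member, best_epoch, best_val)

    return TrainedEnsemble(
        members=members,
        config=cfg,
        task_ids=list(matrix.task_ids),
        label_means=means,
        label_sds=sds,
        registry_fingerprint="",
        audit={
            "run_label": run_label,
            "n_train": int(len(train_idx)),
            "n_validation": int(len(val_idx)),
            "steps_per_epoch": steps_per_epoch,
            "members": member_audits,
        },
    )


def predict(
    ensemble: TrainedEnsemble,
    molecules: Sequence[Molecule],
    graphs: Optional[Sequence[MolecularGraph]] = None,
    chunk_size: int = 200,
) -> PredictionTable:
    """Ensemble-mean model-scale predictions for a list of molecules."""
    cfg = ensemble.config
    if graphs is None:
        graphs = featurize_library(molecules, cfg.featurizer)
    graphs = list(graphs)
    n = len(graphs)
    n_tasks = len(ensemble.task_ids)
    member_out = np.zeros((len(ensemble.members), n, n_tasks))
    for s in range(0, n, chunk_size):
        batch = batch_graphs(graphs[s:s + chunk_size])
        for k, params in enumerate(ensemble.members):
            out, _ = nn.forward(batch, params, cfg.message_passing_depth)
            member_out[k, s:s + len(batch.atoms_per_mol)] = out
    member_out = member_out * ensemble.label_sds + ensemble.label_means
    return PredictionTable(
        compound_ids=[m.compound_id for m in molecules],
        task_ids=list(ensemble.task_ids),
        values=member_out.mean(axis=0),
        spread=member_out.std(axis=0),
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(ensemble: TrainedEnsemble, path: str | Path) -> None:
    """Self-describing archive: weights + config + task registry hash."""
    path = Path(path)
    arrays = {}
    for k, params in enumerate(ensemble.members):
        for name, arr in params.items():
            arrays[f"member{k}/{name}"] = arr
    meta = {
        "config": {**asdict(ensemble.config),
                   "featurizer": asdict(ensemble.config.featurizer)},
        "task_ids": ensemble.task_ids,
        "label_means": ensemble.label_means.tolist(),
        "label_sds": ensemble.label_sds.tolist(),
        "registry_fingerprint": ensemble.registry_fingerprint,
        "audit": ensemble.audit,
        "n_members": len(ensemble.members),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> TrainedEnsemble:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        members = []
        for k in range(meta["n_members"]):
            prefix = f"member{k}/"
            members.append({
                key[len(prefix):]: data[key] for key in data.files if key.startswith(prefix)
            })
    cfg_dict = dict(meta["config"])
    feat = FeaturizerConfig(
        elements=tuple(cfg_dict["featurizer"]["elements"]),
        max_degree=cfg_dict["featurizer"]["max_degree"],
        charges=tuple(cfg_dict["featurizer"]["charges"]),
        max_num_hs=cfg_dict["featurizer"]["max_num_hs"],
    )
    cfg_dict["featurizer"] = feat
    cfg = ModelConfig(**cfg_dict)
    return TrainedEnsemble(
        members=members,
        config=cfg,
        task_ids=list(meta["task_ids"]),
        label_means=np.asarray(meta["label_means"]),
        label_sds=np.asarray(meta["label_sds"]),
        registry_fingerprint=meta["registry_fingerprint"],
        audit=meta["audit"],
    )
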
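"""Synthetic study generator: modality-structured molecule libraries and
sparse, noisy multi-task assay readouts with known ground truth.

The generator emulates the structure of a pharma ADME data set without any
proprietary values: three modality classes (molecular glues,
heterobifunctional degraders, and conventional drug-like compounds), with
heterobifunctionals assembled as warhead-linker-E3-ligand chains and hence
systematically larger and beyond the rule of five; per-task label sparsity;
replicate measurements; censored ('<'/'>') readouts; and registration dates
spanning a temporal-split cutoff.

Ground-truth property values are deterministic functions of the Ro5
descriptor block: a per-model-group latent factor (shared by tasks of the
group, which is what makes multi-task learning advantageous), a small
task-specific linear term, a smooth tanh nonlinearity, and additive modality
offsets. Noise is Gaussian on the model (log) scale, so an oracle predictor
has expected held-out MAE sigma*sqrt(2/pi) in closed form.

All randomness flows from ``GeneratorConfig.seed`` through numpy's PCG64
generator; identical configs reproduce libraries and readouts bit for bit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from rdkit import Chem

from .assay_data import AssayMeasurement
from .chemistry import DESCRIPTOR_NAMES, Molecule, compute_descriptors
from .tasks import TaskSpec, default_registry

MODALITY_ORDER = ("heterobifunctional", "glue", "other")


def load_fragment_pools() -> dict[str, list[str]]:
    """The curated fragment pools shipped with the package."""
    text = resources.files("tpd_qspr.data").joinpath("fragments.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic data set."""

    n_per_modality: Mapping[str, int]
    noise_sd: float | Mapping[str, float] = 0.3
    sparsity: float | Mapping[str, float] = 0.8
    replicate_rate: float = 0.1
    qualifier_rate: float = 0.05
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2020, 1, 1), _dt.date(2023, 7, 13))
    seed: int = 0
    fragment_pools: Optional[Mapping[str, Sequence[str]]] = None
    rng_algorithm: str = "PCG64"  # numpy default_rng; named for reproducibility

    def __post_init__(self) -> None:
        for m, n in self.n_per_modality.items():
            if m not in MODALITY_ORDER:
                raise ValueError(f"unknown modality {m!r}")
            if n < 0:
                raise ValueError("n_per_modality must be >= 0")
        if self.replicate_rate < 0 or self.qualifier_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("empty date range")

    def task_noise_sd(self, task_id: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[task_id])
        return float(self.noise_sd)

    def task_sparsity(self, task_id: str) -> float:
        p = self.sparsity[task_id] if isinstance(self.sparsity, Mapping) else self.sparsity
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"sparsity for {task_id} outside [0, 1]")
        return float(p)


def _pools(cfg: GeneratorConfig) -> dict[str, list[str]]:
    pools = dict(cfg.fragment_pools) if cfg.fragment_pools else load_fragment_pools()
    for name, pool in pools.items():
        if not pool:
            raise ValueError(f"fragment pool {name!r} is empty")
        for frag in pool:
            if Chem.MolFromSmiles(frag) is None:
                raise ValueError(f"invalid fragment SMILES in pool {name!r}: {frag!r}")
    return pools


def _chainable(pool: Sequence[str]) -> list[str]:
    """Fragments whose string-final atom still has a free valence, i.e. that
    can sit in a non-terminal position of a concatenated assembly."""
    out = []
    for frag in pool:
        base = Chem.MolFromSmiles(frag)
        grown = Chem.MolFromSmiles(frag + "C")
        if base is not None and grown is not None \
                and grown.GetNumAtoms() == base.GetNumAtoms() + 1:
            out.append(frag)
    return out


def generate_library(cfg: GeneratorConfig) -> list[Molecule]:
    """Assemble the molecule library for the configured study.

    Heterobifunctionals are warhead + one-or-two linkers + E3-ligand
    concatenations; glues and 'other' compounds are cores decorated with one
    to three substituents (non-terminal decorations drawn from the
    chainable subset of the pool). Registration dates are uniform over the
    configured range. Deterministic under the seed.
    """
    pools = _pools(cfg)
    chain_subs = _chainable(pools["substituents"])
    rng = np.random.default_rng(cfg.seed)
    start, end = cfg.date_range
    n_days = (end - start).days
    molecules: list[Molecule] = []
    serial = 0
    for modality in MODALITY_ORDER:
        n = int(cfg.n_per_modality.get(modality, 0))
        for _ in range(n):
            if modality == "heterobifunctional":
                n_link = 1 + int(rng.random() < 0.5)
                parts = (
                    pools["warheads"][rng.integers(len(pools["warheads"]))],
                    *(pools["linkers"][rng.integers(len(pools["linkers"]))]
                      for _ in range(n_link)),
                    pools["e3_ligands"][rng.integers(len(pools["e3_ligands"]))],
                )
            else:
                core_pool = pools["glue_cores" if modality == "glue" else "drug_cores"]
                n_subs = int(rng.integers(1, 4))
                parts = (
                    core_pool[rng.integers(len(core_pool))],
                    *(chain_subs[rng.integers(len(chain_subs))]
                      for _ in range(n_subs - 1)),
                    pools["substituents"][rng.integers(len(pools["substituents"]))],
                )
            smiles = "".join(parts)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:  # pools are validated, so this indicates a bad pool
                raise ValueError(f"fragment assembly produced invalid SMILES: {smiles!r}")
            serial += 1
            molecules.append(
                Molecule(
                    compound_id=f"CPD-{serial:06d}",
                    structure=Chem.MolToSmiles(mol),
                    modality=modality,
                    registration_date=start + _dt.timedelta(days=int(rng.integers(n_days + 1))),
                )
            )
    return molecules


@dataclass(frozen=True)
class TaskTruthParams:
    """Deterministic ground-truth function for one task.

    value = mu + loading * (group_weights . z) + task_weights . z
          + tanh_amp * tanh(tanh_weights . z) + offsets[modality]

    where z is the z-scored descriptor vector (mw, hba, hbd, tpsa, clogp,
    rotatable bonds).
    """

    mu: float
    loading: float
    group_weights: tuple[float, ...]
    task_weights: tuple[float, ...] = (0.0,) * 6
    tanh_weights: tuple[float, ...] = (0.0,) * 6
    tanh_amp: float = 0.0
    offsets: Mapping[str, float] = field(default_factory=dict)


# Latent-factor directions per model group over z-scored descriptors,
# signs chosen by pharmacology: permeability falls with TPSA/HBD and rises
# with lipophilicity; clearance and CYP engagement rise with lipophilicity;
# the binding/lipophilicity factor is cLogP-dominated.
GROUP_LATENT_WEIGHTS: dict[str, tuple[float, ...]] = {
    "permeability": (-0.25, -0.10, -0.35, -0.55, 0.35, -0.25),
    "clearance": (0.35, -0.20, 0.10, -0.30, 0.50, 0.30),
    "binding_lipophilicity": (0.15, -0.15, -0.10, -0.35, 0.60, 0.10),
    "cyp_inhibition": (0.10, 0.35, -0.30, 0.20, 0.45, -0.20),
}

# A-priori truth parameters for the six standard-study tasks. Means sit near
# the middle of each task's risk band so the three classes are all occupied;
# heterobifunctional offsets encode the systematic bRo5 behaviour (lower
# permeability, higher clearance/CYP engagement, higher LogD).
STANDARD_TRUTH_PARAMS: dict[str, TaskTruthParams] = {
    "LE-MDCK_v2_Papp": TaskTruthParams(
        mu=0.55, loading=0.55, group_weights=GROUP_LATENT_WEIGHTS["permeability"],
        tanh_amp=0.20, offsets={"glue": -0.05, "heterobifunctional": -0.55, "other": 0.0},
    ),
    "RLM_CLint": TaskTruthParams(
        mu=2.25, loading=0.50, group_weights=GROUP_LATENT_WEIGHTS["clearance"],
        tanh_amp=0.20, offsets={"glue": 0.05, "heterobifunctional": 0.45, "other": 0.0},
    ),
    "HLM_CLint": TaskTruthParams(
        mu=2.20, loading=0.50, group_weights=GROUP_LATENT_WEIGHTS["clearance"],
        tanh_amp=0.20, offsets={"glue": 0.05, "heterobifunctional": 0.50, "other": 0.0},
    ),
    "CYP3A4_kobs": TaskTruthParams(
        mu=-1.80, loading=0.40, group_weights=GROUP_LATENT_WEIGHTS["cyp_inhibition"],
        tanh_amp=0.15, offsets={"glue": 0.0, "heterobifunctional": 0.40, "other": 0.0},
    ),
    "CYP3A4_IC50": TaskTruthParams(
        mu=5.50, loading=0.55, group_weights=GROUP_LATENT_WEIGHTS["cyp_inhibition"],
        tanh_amp=0.20, offsets={"glue": 0.05, "heterobifunctional": 0.45, "other": 0.0},
    ),
    "LogD": TaskTruthParams(
        mu=2.40, loading=0.90, group_weights=GROUP_LATENT_WEIGHTS["binding_lipophilicity"],
        tanh_amp=0.25, offsets={"glue": 0.10, "heterobifunctional": 0.60, "other": 0.0},
    ),
}


@dataclass
class GroundTruth:
    """Planted noiseless model-scale values plus everything to recompute them."""

    compound_ids: list[str]
    registry: list[TaskSpec]
    values: np.ndarray  # (n_compounds, n_tasks) noiseless model-scale values
    params: dict[str, TaskTruthParams]
    descriptor_means: np.ndarray
    descriptor_sds: np.ndarray
    modalities: list[str]

    @property
    def task_ids(self) -> list[str]:
        return [s.task_id for s in self.registry]

    def column(self, task_id: str) -> np.ndarray:
        return self.values[:, self.task_ids.index(task_id)]


def _draw_task_params(spec: TaskSpec, rng: np.random.Generator) -> TaskTruthParams:
    """Seeded fallback for tasks without hand-set standard parameters."""
    u = rng.normal(0.0, 0.2 / np.sqrt(6), size=6)
    v = rng.normal(size=6)
    v /= np.linalg.norm(v)
    mu = {"log10": 1.0, "identity": 2.0, "neg_log10_molar": 5.5}[spec.transform]
    return TaskTruthParams(
        mu=mu + float(rng.normal(0.0, 0.3)),
        loading=float(rng.uniform(0.4, 0.8)),
        group_weights=GROUP_LATENT_WEIGHTS[spec.model_group],
        task_weights=tuple(u),
        tanh_weights=tuple(v),
        tanh_amp=float(rng.uniform(0.1, 0.25)),
        offsets={"glue": float(rng.normal(0.0, 0.1)),
                 "heterobifunctional": float(rng.normal(0.0, 0.4)),
                 "other": 0.0},
    )


def plant_ground_truth(
    library: Sequence[Molecule],
    registry: Sequence[TaskSpec],
    cfg: GeneratorConfig,
    params_override: Mapping[str, TaskTruthParams] | None = None,
) -> GroundTruth:
    """Attach deterministic noiseless property values to a library.

    Standard-study tasks use the fixed :data:`STANDARD_TRUTH_PARAMS`;
    other tasks draw parameters from a seeded generator. Task-specific
    linear and tanh directions are always seeded so that within-group tasks
    correlate without being identical.
    """
    desc = np.stack([compute_descriptors(m).as_vector() for m in library])
    means = desc.mean(axis=0)
    sds = desc.std(axis=0)
    sds[sds == 0] = 1.0
    z = (desc - means) / sds

    rng = np.random.default_rng([cfg.seed, 7])
    params: dict[str, TaskTruthParams] = {}
    for spec in registry:
        if params_override and spec.task_id in params_override:
            params[spec.task_id] = params_override[spec.task_id]
            continue
        base = STANDARD_TRUTH_PARAMS.get(spec.task_id)
        if base is None:
            params[spec.task_id] = _draw_task_params(spec, rng)
        else:
            # seeded task-specific directions on top of the fixed parameters
            u = rng.normal(0.0, 0.2 / np.sqrt(6), size=6)
            v = rng.normal(size=6)
            v /= np.linalg.norm(v)
            params[spec.task_id] = replace(base, task_weights=tuple(u), tanh_weights=tuple(v))

    values = np.zeros((len(library), len(registry)))
    modalities = [m.modality for m in library]
    for j, spec in enumerate(registry):
        p = params[spec.task_id]
        w = np.asarray(p.group_weights)
        w = w / np.linalg.norm(w)
        latent = z @ w
        col = (
            p.mu
            + p.loading * latent
            + z @ np.asarray(p.task_weights)
            + p.tanh_amp * np.tanh(z @ np.asarray(p.tanh_weights))
        )
        col += np.array([p.offsets.get(m, 0.0) for m in modalities])
        values[:, j] = col
    return GroundTruth(
        compound_ids=[m.compound_id for m in library],
        registry=list(registry),
        values=values,
        params=params,
        descriptor_means=means,
        descriptor_sds=sds,
        modalities=modalities,
    )


def simulate_readouts(
    truth: GroundTruth,
    cfg: GeneratorConfig,
    library: Sequence[Molecule] | None = None,
) -> list[AssayMeasurement]:
    """Draw sparse noisy raw-scale measurement records from the truth.

    Per (compound, task): observed with probability ``sparsity``; one extra
    replicate with probability ``replicate_rate``; Gaussian noise with the
    task's ``noise_sd`` added on model scale and back-transformed; a record
    becomes censored ('<' below / '>' above the task mean) with probability
    ``qualifier_rate``. Measurement dates follow registration by 0-120 days.
    """
    rng = np.random.default_rng([cfg.seed, 13])
    reg_dates = {m.compound_id: m.registration_date for m in library} if library else {}
    end = cfg.date_range[1]
    records: list[AssayMeasurement] = []
    for j, spec in enumerate(truth.registry):
        sd = cfg.task_noise_sd(spec.task_id)
        p_obs = cfg.task_sparsity(spec.task_id)
        task_mean = float(truth.values[:, j].mean())
        for i, cid in enumerate(truth.compound_ids):
            if rng.random() >= p_obs:
                continue
            n_rep = 1 + (rng.random() < cfg.replicate_rate)
            for _ in range(n_rep):
                model_val = truth.values[i, j] + rng.normal(0.0, sd)
                qualifier = "exact"
                if rng.random() < cfg.qualifier_rate:
                    qualifier = "less_than" if model_val < task_mean else "greater_than"
                measured = None
                if cid in reg_dates:
                    measured = reg_dates[cid] + _dt.timedelta(days=int(rng.integers(121)))
                    measured = min(measured, end)
                records.append(
                    AssayMeasurement(
                        compound_id=cid,
                        task_id=spec.task_id,
                        raw_value=spec.from_model_scale(float(model_val)),
                        qualifier=qualifier,
                        measured_date=measured,
                    )
                )
    return records


@dataclass
class SyntheticStudy:
    """A complete generated study: library, truth, and raw records."""

    cfg: GeneratorConfig
    registry: list[TaskSpec]
    molecules: list[Molecule]
    truth: GroundTruth
    records: list[AssayMeasurement]


def generate_study(cfg: GeneratorConfig, registry: Sequence[TaskSpec]) -> SyntheticStudy:
    library = generate_library(cfg)
    truth = plant_ground_truth(library, registry, cfg)
    records = simulate_readouts(truth, cfg, library)
    return SyntheticStudy(cfg=cfg, registry=list(registry), molecules=library,
                          truth=truth, records=records)


# ---------------------------------------------------------------------------
# Standard study conditions
# ---------------------------------------------------------------------------

#: Task subset of the standard synthetic study: the five risk-thresholded
#: endpoints plus LogD, spanning all four model groups.
STANDARD_TASK_IDS = (
    "LE-MDCK_v2_Papp", "RLM_CLint", "HLM_CLint", "CYP3A4_kobs", "CYP3A4_IC50", "LogD",
)

STANDARD_SPARSITY = {
    "LE-MDCK_v2_Papp": 0.90, "RLM_CLint": 0.80, "HLM_CLint": 0.80,
    "CYP3A4_kobs": 0.50, "CYP3A4_IC50": 0.60, "LogD": 0.85,
}

#: Temporal cutoff of the standard study (train <= cutoff < test).
STANDARD_CUTOFF = _dt.date(2021, 12, 31)


def standard_task_registry() -> list[TaskSpec]:
    by_id = {s.task_id: s for s in default_registry()}
    return [by_id[t] for t in STANDARD_TASK_IDS]


def standard_study_config(seed: int, n_total: int = 5000) -> GeneratorConfig:
    """The standard synthetic study: 5000 compounds (30% heterobifunctional,
    35% glues, 35% other), 6 tasks, noise sd 0.3 on model scale."""
    n_het = int(round(0.30 * n_total))
    n_glue = int(round(0.35 * n_total))
    n_other = n_total - n_het - n_glue
    return GeneratorConfig(
        n_per_modality={"heterobifunctional": n_het, "glue": n_glue, "other": n_other},
        noise_sd=0.3,
        sparsity=dict(STANDARD_SPARSITY),
        replicate_rate=0.1,
        qualifier_rate=0.05,
        date_range=(_dt.date(2020, 1, 1), _dt.date(2023, 7, 13)),
        seed=seed,
    )
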
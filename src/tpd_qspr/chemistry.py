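"""Structure handling: standardization, descriptors, fingerprints, scaffolds,
and 2-D chemical-space embedding.

Compound structures enter as SMILES and are standardized with a fixed
sequence of RDKit ``rdMolStandardize`` operations (explicit-hydrogen removal,
metal disconnection, normalization, reionization, stereochemistry
assignment) followed by canonicalization. The Ro5 descriptor block (MW, HBA,
HBD, TPSA, cLogP, rotatable bonds) drives both the beyond-rule-of-five flag
and the synthetic ground-truth property functions. Chemical space is
summarized with 166-bit MACCS keys, Tanimoto distances, and a UMAP
projection.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

MODALITIES = ("glue", "heterobifunctional", "other")

#: Designated scaffold key for acyclic molecules (no ring framework).
EMPTY_SCAFFOLD = ""

MACCS_N_BITS = 166


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the input."""

    def __init__(self, smiles: str, detail: str = "") -> None:
        self.smiles = smiles
        msg = f"could not parse SMILES {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass(frozen=True)
class Molecule:
    """A registered compound: id, canonical structure, modality, date."""

    compound_id: str
    structure: str
    modality: Literal["glue", "heterobifunctional", "other"]
    registration_date: _dt.date

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass(frozen=True)
class StandardizationPolicy:
    """Configuration of the structure standardization cascade.

    ``desalt`` keeps only the largest organic fragment; off by default so
    that counter-ions survive metal disconnection unless explicitly removed.
    """

    desalt: bool = False
    assign_stereo: bool = True


def standardize_structure(raw: str, policy: StandardizationPolicy | None = None) -> str:
    """Standardize and canonicalize a SMILES string.

    The cascade runs, in order: explicit-hydrogen removal, metal
    disconnection, normalization, reionization, stereochemistry assignment,
    canonicalization. Idempotent: re-standardizing the output is a no-op.
    """
    if not raw or not raw.strip():
        raise StructureParseError(raw, "empty input")
    policy = policy or StandardizationPolicy()
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StructureParseError(raw)
    mol = Chem.RemoveHs(mol)
    mol = rdMolStandardize.MetalDisconnector().Disconnect(mol)
    mol = rdMolStandardize.Normalize(mol)
    mol = rdMolStandardize.Reionize(mol)
    if policy.desalt:
        mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    if policy.assign_stereo:
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return Chem.MolToSmiles(mol)


def _mol_from_structure(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(structure)
    return mol


@dataclass(frozen=True)
class Ro5Rule:
    """Rule-of-five bounds and the violation count that flags beyond-Ro5.

    Lipinski's original formulation flags compounds violating more than one
    of MW<=500, cLogP<=5, HBD<=5, HBA<=10; set ``min_violations=1`` for the
    stricter single-violation convention.
    """

    mw_max: float = 500.0
    clogp_max: float = 5.0
    hbd_max: int = 5
    hba_max: int = 10
    min_violations: int = 2


@dataclass(frozen=True)
class DescriptorRecord:
    """Ro5 descriptor block for one molecule."""

    mw: float
    hba: int
    hbd: int
    tpsa: float
    clogp: float
    rotatable_bonds: int
    beyond_ro5: bool

    def as_vector(self) -> np.ndarray:
        """Numeric descriptor vector (mw, hba, hbd, tpsa, clogp, rotb)."""
        return np.array(
            [self.mw, self.hba, self.hbd, self.tpsa, self.clogp, self.rotatable_bonds],
            dtype=np.float64,
        )


DESCRIPTOR_NAMES = ("mw", "hba", "hbd", "tpsa", "clogp", "rotatable_bonds")


def ro5_violations(mw: float, clogp: float, hbd: int, hba: int, rule: Ro5Rule) -> int:
    return int(mw > rule.mw_max) + int(clogp > rule.clogp_max) + int(hbd > rule.hbd_max) + int(hba > rule.hba_max)


def compute_descriptors(structure: str | Molecule, rule: Ro5Rule | None = None) -> DescriptorRecord:
    """Compute the six Ro5 descriptors and the beyond-Ro5 flag."""
    rule = rule or Ro5Rule()
    smiles = structure.structure if isinstance(structure, Molecule) else structure
    mol = _mol_from_structure(smiles)
    try:
        mw = Descriptors.MolWt(mol)
        hba = Lipinski.NumHAcceptors(mol)
        hbd = Lipinski.NumHDonors(mol)
        tpsa = rdMolDescriptors.CalcTPSA(mol)
        clogp = Crippen.MolLogP(mol)
        rotb = Lipinski.NumRotatableBonds(mol)
    except Exception as exc:  # pragma: no cover - descriptor engine failure
        raise RuntimeError(f"descriptor computation failed for {smiles!r}: {exc}") from exc
    beyond = ro5_violations(mw, clogp, hbd, hba, rule) >= rule.min_violations
    return DescriptorRecord(
        mw=float(mw), hba=int(hba), hbd=int(hbd), tpsa=float(tpsa),
        clogp=float(clogp), rotatable_bonds=int(rotb), beyond_ro5=bool(beyond),
    )


def descriptor_table(molecules: Sequence[Molecule], rule: Ro5Rule | None = None):
    """Descriptor DataFrame for a library (one row per molecule)."""
    import pandas as pd

    rows = []
    for m in molecules:
        rec = compute_descriptors(m, rule)
        rows.append({
            "compound_id": m.compound_id, "modality": m.modality,
            "mw": rec.mw, "hba": rec.hba, "hbd": rec.hbd, "tpsa": rec.tpsa,
            "clogp": rec.clogp, "rotatable_bonds": rec.rotatable_bonds,
            "beyond_ro5": rec.beyond_ro5,
        })
    return pd.DataFrame(rows)


def maccs_fingerprint(structure: str | Molecule) -> np.ndarray:
    """166-bit MACCS keys as a boolean vector (RDKit's unused bit 0 dropped)."""
    smiles = structure.structure if isinstance(structure, Molecule) else structure
    mol = _mol_from_structure(smiles)
    bv = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(bv.GetNumBits(), dtype=bool)
    for bit in bv.GetOnBits():
        arr[bit] = True
    return arr[1:]  # bit 0 is never set by RDKit's MACCS implementation


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Tanimoto similarity of two equal-length binary fingerprints.

    Two all-zero fingerprints are defined maximally similar (distance 0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        logger.warning("tanimoto_distance of two all-zero fingerprints; returning 0")
        return 0.0
    inter = np.logical_and(a, b).sum()
    return float(1.0 - inter / union)


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distances for a (n, bits) boolean matrix."""
    x = np.asarray(fps, dtype=np.float64)
    inter = x @ x.T
    pop = x.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = 1.0 - np.where(union > 0, inter / union, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def scaffold_key(structure: str | Molecule) -> str:
    """Bemis-Murcko framework SMILES; acyclic molecules map to the
    designated empty-scaffold key."""
    smiles = structure.structure if isinstance(structure, Molecule) else structure
    _mol_from_structure(smiles)  # propagate parse failures explicitly
    key = MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)
    return key if key else EMPTY_SCAFFOLD


@dataclass(frozen=True)
class EmbeddingConfig:
    """UMAP settings for the chemical-space projection."""

    n_neighbors: int = 15
    min_dist: float = 0.1


def embed_chemical_space(
    fps: Sequence[np.ndarray] | np.ndarray,
    config: EmbeddingConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP embedding of fingerprints under the Tanimoto metric.

    Duplicate fingerprints are embedded once and share coordinates; output
    is deterministic for a fixed seed.
    """
    config = config or EmbeddingConfig()
    x = np.asarray([np.asarray(f, dtype=bool) for f in fps])
    if x.ndim != 2 or x.shape[0] < 10:
        raise ValueError("need at least 10 fingerprints to embed")
    # Deduplicate so identical fingerprints provably share coordinates.
    uniq, inverse = np.unique(x, axis=0, return_inverse=True)
    dist = tanimoto_distance_matrix(uniq)
    n_neighbors = min(config.n_neighbors, max(2, uniq.shape[0] - 1))

    import umap  # deferred: numba-backed import is expensive

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=config.min_dist,
        metric="precomputed",
        random_state=seed,
        n_jobs=1,
    )
    coords_uniq = reducer.fit_transform(dist)
    return np.asarray(coords_uniq, dtype=np.float64)[inverse]
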
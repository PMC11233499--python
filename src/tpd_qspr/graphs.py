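"""Molecular graph featurization for the message-passing network.

A molecule becomes a directed graph over heavy atoms: every bond
contributes two directed edges. Atom features are one-hot element, degree,
formal charge, attached-hydrogen count, plus aromaticity/ring flags and a
scaled atomic mass; bond features are one-hot bond order plus
conjugation/ring flags. Features are deterministic for a given canonical
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemistry import Molecule, StructureParseError


class FeaturizationError(ValueError):
    """Unsupported atom or malformed structure during featurization."""


@dataclass(frozen=True)
class FeaturizerConfig:
    """Feature vocabulary; dimensions are fixed by this config."""

    elements: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B", "Si")
    max_degree: int = 5
    charges: tuple[int, ...] = (-2, -1, 0, 1, 2)
    max_num_hs: int = 4

    @property
    def atom_dim(self) -> int:
        return len(self.elements) + (self.max_degree + 1) + len(self.charges) \
            + (self.max_num_hs + 1) + 3  # aromatic, in-ring, mass/100

    @property
    def bond_dim(self) -> int:
        return 6  # single, double, triple, aromatic, conjugated, in-ring


@dataclass
class MolecularGraph:
    """Directed-bond graph of one molecule (heavy atoms only)."""

    atom_features: np.ndarray   # (n_atoms, atom_dim) float32
    bond_features: np.ndarray   # (n_bonds*2, bond_dim) float32
    src: np.ndarray             # (n_bonds*2,) int32: source atom of directed bond
    dst: np.ndarray             # (n_bonds*2,) int32: destination atom
    rev: np.ndarray             # (n_bonds*2,) int32: index of the reverse bond

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_directed_bonds(self) -> int:
        return self.bond_features.shape[0]


def _one_hot(value, choices) -> list[float]:
    return [1.0 if value == c else 0.0 for c in choices]


def featurize(mol: Molecule | str, config: FeaturizerConfig | None = None) -> MolecularGraph:
    """Featurize a molecule into a directed-bond graph."""
    config = config or FeaturizerConfig()
    smiles = mol.structure if isinstance(mol, Molecule) else mol
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise StructureParseError(smiles)

    atom_rows = []
    for atom in rdmol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in config.elements:
            raise FeaturizationError(
                f"unsupported element {symbol!r} in {smiles!r}"
            )
        row = (
            _one_hot(symbol, config.elements)
            + _one_hot(min(atom.GetDegree(), config.max_degree), range(config.max_degree + 1))
            + _one_hot(atom.GetFormalCharge(), config.charges)
            + _one_hot(min(atom.GetTotalNumHs(), config.max_num_hs), range(config.max_num_hs + 1))
            + [float(atom.GetIsAromatic()), float(atom.IsInRing()), atom.GetMass() / 100.0]
        )
        atom_rows.append(row)
    atom_features = np.asarray(atom_rows, dtype=np.float32)

    bond_rows, src, dst = [], [], []
    for bond in rdmol.GetBonds():
        bt = bond.GetBondType()
        row = [
            float(bt == Chem.BondType.SINGLE),
            float(bt == Chem.BondType.DOUBLE),
            float(bt == Chem.BondType.TRIPLE),
            float(bt == Chem.BondType.AROMATIC),
            float(bond.GetIsConjugated()),
            float(bond.IsInRing()),
        ]
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bond_rows.extend([row, row])
        src.extend([a, b])
        dst.extend([b, a])
    n_dir = len(bond_rows)
    rev = np.arange(n_dir, dtype=np.int32)
    rev[0::2] += 1
    rev[1::2] -= 1
    return MolecularGraph(
        atom_features=atom_features,
        bond_features=np.asarray(bond_rows, dtype=np.float32).reshape(n_dir, config.bond_dim),
        src=np.asarray(src, dtype=np.int32),
        dst=np.asarray(dst, dtype=np.int32),
        rev=rev,
    )


@dataclass
class BatchedGraph:
    """Disjoint union of molecular graphs for minibatch processing."""

    atom_features: np.ndarray
    bond_features: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    rev: np.ndarray
    mol_index: np.ndarray       # (n_atoms,) int32: owning molecule per atom
    n_mols: int
    atoms_per_mol: np.ndarray   # (n_mols,) int32


def batch_graphs(graphs: Sequence[MolecularGraph]) -> BatchedGraph:
    atom_offsets = np.cumsum([0] + [g.n_atoms for g in graphs[:-1]])
    bond_offsets = np.cumsum([0] + [g.n_directed_bonds for g in graphs[:-1]])
    atom_features = np.concatenate([g.atom_features for g in graphs], axis=0)
    bond_features = (
        np.concatenate([g.bond_features for g in graphs], axis=0)
        if any(g.n_directed_bonds for g in graphs)
        else np.zeros((0, graphs[0].bond_features.shape[1]), dtype=np.float32)
    )
    src = np.concatenate([g.src + off for g, off in zip(graphs, atom_offsets)]).astype(np.int32)
    dst = np.concatenate([g.dst + off for g, off in zip(graphs, atom_offsets)]).astype(np.int32)
    rev = np.concatenate([g.rev + off for g, off in zip(graphs, bond_offsets)]).astype(np.int32)
    mol_index = np.concatenate(
        [np.full(g.n_atoms, i, dtype=np.int32) for i, g in enumerate(graphs)]
    )
    return BatchedGraph(
        atom_features=atom_features,
        bond_features=bond_features,
        src=src,
        dst=dst,
        rev=rev,
        mol_index=mol_index,
        n_mols=len(graphs),
        atoms_per_mol=np.asarray([g.n_atoms for g in graphs], dtype=np.int32),
    )
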
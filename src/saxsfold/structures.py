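"""Atomic structures and conformer ensembles.

The central container is :class:`AtomicStructure`: a flat array-of-atoms view
of one model of a protein, carrying per-atom element symbols, electron counts,
Cartesian coordinates in Angstrom, and chain/residue bookkeeping.  A
multi-model (e.g. solution NMR) deposition becomes a
:class:`ConformerEnsemble` — an ordered list of structures sharing one
sequence and numbering.

Electron counts default to atomic numbers.  Hydrogens absent from a file are
not imputed by default; an optional united-atom mode folds the implicit
hydrogens of the 20 standard amino acids into their bonded heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, MalformedEnsembleError

# Atomic numbers for the elements that occur in protein/nucleic structures
# plus common ions; extend as needed.
ELEMENT_Z: dict[str, int] = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Implicit hydrogen counts per (residue, heavy-atom name) for united-atom
# electron weighting.  Backbone N carries one H (none for proline), CA one
# (two for glycine); carbonyl C/O carry none.  Ionizable groups are counted
# in their neutral-pH dominant form.
_BACKBONE_H = {"N": 1, "CA": 1, "C": 0, "O": 0, "OXT": 0}
_SIDECHAIN_H: dict[str, dict[str, int]] = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
    "ASP": {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
    "CYS": {"CB": 2, "SG": 1},
    "GLN": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
    "GLY": {},
    "HIS": {"CB": 2, "CG": 0, "ND1": 1, "CD2": 1, "CE1": 1, "NE2": 0},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
    "PHE": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 0, "NE1": 1, "CE2": 0,
            "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1},
    "TYR": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1,
            "CZ": 0, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
}


def implicit_hydrogens(res_name: str, atom_name: str) -> int:
    """Number of hydrogens bonded to a heavy atom in the standard amino acids.

    Unknown residues or atom names contribute zero.
    """
    if atom_name in _BACKBONE_H:
        if res_name == "PRO" and atom_name == "N":
            return 0
        if res_name == "GLY" and atom_name == "CA":
            return 2
        return _BACKBONE_H[atom_name]
    return _SIDECHAIN_H.get(res_name, {}).get(atom_name, 0)


@dataclass
class AtomicStructure:
    """One model of a molecule as parallel per-atom arrays.

    Parameters
    ----------
    elements : element symbols, upper-case.
    z : electron count per atom (atomic number by default).
    coords : (n_atoms, 3) Cartesian coordinates, Angstrom.
    chain_ids, res_indices, res_names, atom_names : per-atom bookkeeping.
    model_id : model number (1-based for multi-model files).
    """

    elements: list[str]
    z: np.ndarray
    coords: np.ndarray
    chain_ids: list[str]
    res_indices: np.ndarray
    res_names: list[str]
    atom_names: list[str] = field(default_factory=list)
    model_id: int = 1

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DegenerateInputError("coords must be an (n, 3) array")
        self.res_indices = np.asarray(self.res_indices, dtype=np.int64)
        if not self.atom_names:
            self.atom_names = ["CA"] * len(self.elements)
        n = len(self.elements)
        if not (len(self.z) == len(self.coords) == len(self.chain_ids)
                == len(self.res_indices) == len(self.res_names)
                == len(self.atom_names) == n):
            raise DegenerateInputError("per-atom arrays have inconsistent lengths")
        if n and (self.z < 1).any():
            raise DegenerateInputError("every atom must carry at least one electron")
        if n and not np.isfinite(self.coords).all():
            raise DegenerateInputError("non-finite coordinates")
        # residue indices must be non-decreasing atom-to-atom within a chain
        for cid in set(self.chain_ids):
            mask = np.array([c == cid for c in self.chain_ids])
            idx = self.res_indices[mask]
            if len(idx) > 1 and (np.diff(idx) < 0).any():
                raise DegenerateInputError(
                    f"residue indices decrease within chain {cid!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_residues(self) -> int:
        return len({(c, int(r)) for c, r in zip(self.chain_ids, self.res_indices)})

    def sequence(self, chain_id: str | None = None) -> str:
        """One-letter sequence of one chain (or the whole structure in order)."""
        seen: list[tuple[str, int]] = []
        letters: list[str] = []
        for c, r, name in zip(self.chain_ids, self.res_indices, self.res_names):
            if chain_id is not None and c != chain_id:
                continue
            key = (c, int(r))
            if key not in seen:
                seen.append(key)
                letters.append(THREE_TO_ONE.get(name, "X"))
        return "".join(letters)

    def ca_coords(self) -> np.ndarray:
        """Coordinates of CA atoms, in residue order."""
        mask = [name == "CA" for name in self.atom_names]
        return self.coords[np.asarray(mask, dtype=bool)]

    def united_atom_z(self) -> np.ndarray:
        """Electron counts with implicit hydrogens folded into heavy atoms."""
        extra = np.array(
            [implicit_hydrogens(rn, an)
             for rn, an in zip(self.res_names, self.atom_names)],
            dtype=np.int64,
        )
        return self.z + extra

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicStructure":
        """Rigid-body copy: x -> R x + t."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, coords=new)

    @classmethod
    def from_ca(
        cls,
        coords: np.ndarray,
        sequence: str | None = None,
        chain_id: str = "A",
        z: int = 6,
        model_id: int = 1,
    ) -> "AtomicStructure":
        """Build a CA-trace structure from bare coordinates.

        Each coordinate becomes the CA atom of one residue; ``z`` is the
        placeholder electron count (carbon by default).
        """
        coords = np.asarray(coords, dtype=np.float64)
        n = len(coords)
        if sequence is None:
            sequence = "A" * n
        if len(sequence) != n:
            raise DegenerateInputError("sequence length must match residue count")
        return cls(
            elements=["C"] * n,
            z=np.full(n, z, dtype=np.int64),
            coords=coords,
            chain_ids=[chain_id] * n,
            res_indices=np.arange(1, n + 1),
            res_names=[ONE_TO_THREE.get(a, "ALA") for a in sequence],
            atom_names=["CA"] * n,
            model_id=model_id,
        )


@dataclass
class ConformerEnsemble:
    """Ordered conformers of one entry sharing sequence and numbering."""

    entry_id: str
    models: list[AtomicStructure]

    def __post_init__(self) -> None:
        if not self.models:
            raise MalformedEnsembleError(f"{self.entry_id}: ensemble has no models")
        ref = self.models[0].sequence()
        for m in self.models[1:]:
            if m.sequence() != ref:
                raise MalformedEnsembleError(
                    f"{self.entry_id}: model {m.model_id} sequence differs from model "
                    f"{self.models[0].model_id}"
                )

    @property
    def sequence(self) -> str:
        return self.models[0].sequence()

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_residues(self) -> int:
        return self.models[0].n_residues

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)


def pseudo_sequence(n: int, seed: int = 0) -> str:
    """Deterministic pseudo-random amino-acid sequence (for fixtures)."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(rng.choice(alphabet, size=n))
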
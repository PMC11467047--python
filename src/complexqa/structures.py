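"""Normalized structure hierarchy: Structure > Chain > Residue > Atom.

The hierarchy is format-agnostic; parsers in :mod:`complexqa.io_structures`
produce it and everything downstream consumes it. Objects are treated as
immutable after construction (coordinate arrays are cached on first use).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from ._chem import HYDROGEN_ELEMENTS


class MoleculeClass(enum.Enum):
    PROTEIN = "protein"
    PEPTIDE = "peptide"
    NUCLEIC = "nucleic"
    SMALL_MOLECULE = "small_molecule"

    @property
    def is_polymer(self) -> bool:
        return self is not MoleculeClass.SMALL_MOLECULE

    @property
    def is_amino(self) -> bool:
        return self in (MoleculeClass.PROTEIN, MoleculeClass.PEPTIDE)


class FileFormat(enum.Enum):
    PDB = "pdb"
    MMCIF = "mmcif"


@dataclass(frozen=True)
class Atom:
    """A single atom with normalized name, element symbol and coordinates."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(3)
        )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """One residue (or one small-molecule component)."""

    name: str
    seq_num: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    one_letter: str = "-"  # '-' marks non-polymer components

    @property
    def key(self) -> tuple[int, str]:
        """Author residue number + insertion code; unique within a chain."""
        return (self.seq_num, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.name} {self.seq_num}{self.icode}>"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    molecule_class: MoleculeClass = MoleculeClass.PROTEIN

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def residue_by_key(self, key: tuple[int, str]) -> Residue:
        return self._key_index()[key]

    def _key_index(self) -> dict[tuple[int, str], Residue]:
        idx = self.__dict__.get("_key_idx")
        if idx is None:
            idx = {r.key: r for r in self.residues}
            self.__dict__["_key_idx"] = idx
        return idx

    def heavy_coords(self) -> tuple[np.ndarray, list[tuple[int, str]]]:
        """All heavy-atom coordinates plus the owning residue key per atom."""
        cached = self.__dict__.get("_heavy_cache")
        if cached is None:
            coords, keys = [], []
            for res in self.residues:
                for atom in res.heavy_atoms:
                    coords.append(atom.coords)
                    keys.append(res.key)
            arr = (
                np.asarray(coords, dtype=float)
                if coords
                else np.empty((0, 3))
            )
            cached = (arr, keys)
            self.__dict__["_heavy_cache"] = cached
        return cached

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Chain {self.chain_id} {self.molecule_class.value} "
            f"{len(self.residues)} res>"
        )


@dataclass
class Structure:
    chains: dict[str, Chain] = field(default_factory=dict)
    source_path: str = ""
    format: Optional[FileFormat] = None

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains.values())

    def __getitem__(self, chain_id: str) -> Chain:
        return self.chains[chain_id]

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self.chains

    def __len__(self) -> int:
        return len(self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains.keys())

    def add_chain(self, chain: Chain) -> None:
        if chain.chain_id in self.chains:
            raise ValueError(f"duplicate chain id {chain.chain_id!r}")
        self.chains[chain.chain_id] = chain

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self if c.molecule_class.is_polymer]

    def ligand_chains(self) -> list[Chain]:
        return [c for c in self if not c.molecule_class.is_polymer]
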
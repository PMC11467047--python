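"""Reading PDB/mmCIF files into the normalized hierarchy.

Parsing is delegated to Biopython; this module normalizes the result:
hydrogens and waters are dropped, only the highest-occupancy alternate
location is kept, only the first MODEL is read, and non-polymer components
are split into their own single-residue SMALL_MOLECULE chains.
"""

from __future__ import annotations

import gzip
import io
import os
import warnings
from typing import Optional, Union

from Bio.PDB import MMCIFParser, PDBParser

from . import _chem
from .constants import DEFAULT_CONSTANTS
from .errors import (
    ClassificationError,
    EmptyStructureError,
    ParseError,
    UnsupportedOperationError,
)
from .structures import Atom, Chain, FileFormat, MoleculeClass, Residue, Structure

__all__ = ["parse_structure", "classify_chain", "extract_sequence"]

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: str) -> io.TextIOWrapper:
    """Open a possibly gzip-compressed text file transparently."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _detect_format(path: str) -> Optional[FileFormat]:
    base = path[:-3] if path.endswith(".gz") else path
    ext = os.path.splitext(base)[1].lower()
    if ext in (".pdb", ".ent"):
        return FileFormat.PDB
    if ext in (".cif", ".mmcif"):
        return FileFormat.MMCIF
    return None


def _sniff_format(path: str) -> FileFormat:
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("data_", "loop_", "#")):
                return FileFormat.MMCIF
            if stripped.split()[0] in (
                "ATOM", "HETATM", "HEADER", "MODEL", "REMARK", "TITLE",
                "CRYST1", "EXPDTA", "SEQRES", "COMPND",
            ):
                return FileFormat.PDB
            break
    raise ParseError(f"cannot determine file format of {path!r}")


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _pick_altloc(bio_atom):
    """Resolve a (possibly disordered) Biopython atom to one conformer."""
    if not bio_atom.is_disordered():
        return bio_atom
    def sort_key(child):
        occ = child.get_occupancy()
        return (-(occ if occ is not None else 0.0), child.get_altloc())
    return sorted(bio_atom.child_dict.values(), key=sort_key)[0]


def _residue_kind(resname: str, atom_names: set[str]) -> str:
    """'amino' | 'nucleic' | 'other', by component name then backbone atoms."""
    if _chem.is_amino_name(resname):
        return "amino"
    if _chem.is_nucleic_name(resname):
        return "nucleic"
    if {"N", "CA", "C"} <= atom_names:
        return "amino"
    if "C1'" in atom_names and ({"P", "O5'", "O3'"} & atom_names):
        return "nucleic"
    return "other"


def _convert_residue(bio_res) -> Optional[Residue]:
    hetflag, seq_num, icode = bio_res.id
    resname = bio_res.get_resname().strip()
    if hetflag == "W" or resname in _chem.WATER_NAMES:
        return None
    atoms = []
    seen = set()
    for bio_atom in bio_res.get_list():
        atom = _pick_altloc(bio_atom)
        name = atom.get_name().strip()
        element = (atom.element or "").strip().upper() or _guess_element(name)
        if element in _chem.HYDROGEN_ELEMENTS:
            continue
        if name in seen:  # duplicate name after altloc collapse
            continue
        seen.add(name)
        atoms.append(Atom(name=name, element=element, coords=atom.get_coord()))
    if not atoms:
        return None
    return Residue(
        name=resname,
        seq_num=seq_num,
        icode=icode.strip(),
        atoms=atoms,
    )


def parse_structure(
    path: Union[str, "os.PathLike[str]"],
    format_hint: Optional[FileFormat] = None,
    peptide_max_len: int = DEFAULT_CONSTANTS.peptide_max_len,
) -> Structure:
    """Parse a PDB or mmCIF file (optionally gzipped) into a Structure.

    Parameters
    ----------
    path:
        Input file; gzip compression is detected from the magic bytes.
    format_hint:
        Force PDB or mmCIF; otherwise inferred from the extension, falling
        back to content sniffing.
    peptide_max_len:
        Amino-acid chains of at most this length classify as PEPTIDE.
    """
    path = str(path)
    if not os.path.isfile(path):
        raise ParseError(f"structure file not found: {path!r}")
    fmt = format_hint or _detect_format(path) or _sniff_format(path)

    parser = (
        PDBParser(QUIET=True)
        if fmt is FileFormat.PDB
        else MMCIFParser(QUIET=True)
    )
    try:
        with _open_text(path) as fh, warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure("s", fh)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"failed to parse {path!r}: {exc}") from exc

    models = bio_structure.get_list()
    if not models:
        raise EmptyStructureError(f"no models in {path!r}")
    model = models[0]  # MODEL 1 only

    structure = Structure(source_path=path, format=fmt)
    for bio_chain in model.get_list():
        cid = bio_chain.id.strip() or bio_chain.id
        polymer: list[Residue] = []
        ligands: list[Residue] = []
        for bio_res in bio_chain.get_list():
            res = _convert_residue(bio_res)
            if res is None:
                continue
            kind = _residue_kind(res.name, {a.name for a in res.atoms})
            if kind == "other":
                ligands.append(res)
            else:
                res.one_letter = (
                    _chem.amino_one_letter(res.name)
                    if kind == "amino"
                    else _chem.nucleic_one_letter(res.name)
                )
                polymer.append(res)
        if polymer:
            chain = Chain(chain_id=cid, residues=polymer)
            chain.molecule_class = classify_chain(chain, peptide_max_len)
            structure.add_chain(chain)
        for res in ligands:
            # Each non-polymer component becomes its own chain; keep the
            # author id when it is unambiguous.
            if not polymer and len(ligands) == 1:
                lig_id = cid
            else:
                lig_id = f"{cid}_{res.name}{res.seq_num}"
            structure.add_chain(
                Chain(
                    chain_id=lig_id,
                    residues=[res],
                    molecule_class=MoleculeClass.SMALL_MOLECULE,
                )
            )
    if len(structure) == 0:
        raise EmptyStructureError(f"no chains left after normalization: {path!r}")
    return structure


def classify_chain(
    chain: Chain, peptide_max_len: int = DEFAULT_CONSTANTS.peptide_max_len
) -> MoleculeClass:
    """Assign a molecule class to a chain based on its residue composition.

    Raises
    ------
    ClassificationError
        If the chain mixes amino-acid and nucleotide residues.
    """
    if not chain.residues:
        raise ClassificationError(f"chain {chain.chain_id!r} is empty")
    kinds = {
        res.key: _residue_kind(res.name, {a.name for a in res.atoms})
        for res in chain.residues
    }
    distinct = set(kinds.values())
    if distinct <= {"amino"}:
        if len(chain.residues) <= peptide_max_len:
            return MoleculeClass.PEPTIDE
        return MoleculeClass.PROTEIN
    if distinct <= {"nucleic"}:
        return MoleculeClass.NUCLEIC
    if distinct == {"other"} and len(chain.residues) == 1:
        return MoleculeClass.SMALL_MOLECULE
    offending = [
        f"{chain.chain_id}/{res.name}{res.seq_num}"
        for res in chain.residues
        if kinds[res.key] != "amino"
    ]
    raise ClassificationError(
        f"chain {chain.chain_id!r} mixes polymer types; offending residues: "
        + ", ".join(offending)
    )


def extract_sequence(chain: Chain) -> str:
    """One-letter sequence of a polymer chain, in residue order.

    Unknown residues become ``X`` (protein/peptide) or ``N`` (nucleic).
    """
    if chain.molecule_class is MoleculeClass.SMALL_MOLECULE:
        raise UnsupportedOperationError(
            f"chain {chain.chain_id!r} is a small molecule and has no sequence"
        )
    if chain.molecule_class.is_amino:
        return "".join(_chem.amino_one_letter(r.name) for r in chain.residues)
    return "".join(_chem.nucleic_one_letter(r.name) for r in chain.residues)
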
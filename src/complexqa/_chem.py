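"""Residue-name tables: three-to-one letter codes, nucleotides, waters."""

from __future__ import annotations

AMINO_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}

AMINO_1TO3: dict[str, str] = {v: k for k, v in AMINO_3TO1.items() if v != "X"}

# Common chemically modified residues mapped to their parent component.
MODIFIED_PARENT: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "CME": "CYS", "OCS": "CYS",
    "MLY": "LYS", "M3L": "LYS", "KCX": "LYS",
    "HYP": "PRO", "FME": "MET", "PCA": "GLU",
}

NUCLEIC_1: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U", "I": "I", "N": "N",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DI": "I",
    "DN": "N",
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

HYDROGEN_ELEMENTS = frozenset({"H", "D"})


def parent_component(resname: str) -> str:
    """Map a modified residue code to its parent; identity otherwise."""
    return MODIFIED_PARENT.get(resname, resname)


def is_amino_name(resname: str) -> bool:
    return parent_component(resname) in AMINO_3TO1


def is_nucleic_name(resname: str) -> bool:
    return resname in NUCLEIC_1


def amino_one_letter(resname: str) -> str:
    return AMINO_3TO1.get(parent_component(resname), "X")


def nucleic_one_letter(resname: str) -> str:
    return NUCLEIC_1.get(resname, "N")
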
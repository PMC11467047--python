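"""Shared builders for hand-made toy structures.

Tests construct every structure programmatically; nothing is downloaded
and no binary files are written.
"""

from __future__ import annotations

import numpy as np
import pytest

from complexqa.correspondence import MappingMode, ResidueCorrespondence
from complexqa.io_structures import classify_chain
from complexqa.structures import Atom, Chain, Residue, Structure


def protein_residue(
    seq_num: int,
    origin,
    name: str = "ALA",
    with_cb: bool = True,
    with_o: bool = True,
) -> Residue:
    """One amino-acid residue with a fixed local atom arrangement."""
    o = np.asarray(origin, float)
    atoms = [
        Atom("N", "N", o + [-1.2, 0.3, 0.0]),
        Atom("CA", "C", o),
        Atom("C", "C", o + [1.3, 0.5, 0.0]),
    ]
    if with_o:
        atoms.append(Atom("O", "O", o + [1.5, 1.7, 0.2]))
    if with_cb and name != "GLY":
        atoms.append(Atom("CB", "C", o + [-0.3, -1.4, 0.6]))
    return Residue(name=name, seq_num=seq_num, atoms=atoms)


def line_chain(
    chain_id: str,
    n_res: int = 5,
    start=(0.0, 0.0, 0.0),
    step=(3.8, 0.0, 0.0),
    names=None,
    seq_start: int = 1,
    **residue_kwargs,
) -> Chain:
    """Chain of residues placed along a straight line."""
    start = np.asarray(start, float)
    step = np.asarray(step, float)
    residues = [
        protein_residue(
            seq_start + i,
            start + i * step,
            name=(names[i] if names else "ALA"),
            **residue_kwargs,
        )
        for i in range(n_res)
    ]
    chain = Chain(chain_id=chain_id, residues=residues)
    chain.molecule_class = classify_chain(chain)
    return chain


def two_chain_structure(chain_a: Chain, chain_b: Chain, *extra) -> Structure:
    s = Structure(source_path="<test>")
    for chain in (chain_a, chain_b, *extra):
        s.add_chain(chain)
    return s


def identity_correspondence(
    model_chain: Chain, ref_chain: Chain
) -> ResidueCorrespondence:
    """Pair residues positionally (used when both chains match 1:1)."""
    pairs = list(zip(model_chain.residues, ref_chain.residues))
    return ResidueCorrespondence(
        pairs=pairs,
        coverage=len(pairs) / len(ref_chain.residues),
        mode=MappingMode.ALIGNMENT,
        model_chain_id=model_chain.chain_id,
        ref_chain_id=ref_chain.chain_id,
    )


def transform_structure(structure: Structure, rotation, translation) -> Structure:
    """Apply one global rigid transform to every atom (fresh objects)."""
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    out = Structure(source_path=structure.source_path)
    for chain in structure:
        residues = []
        for res in chain.residues:
            atoms = [
                Atom(a.name, a.element, rotation @ a.coords + translation)
                for a in res.atoms
            ]
            residues.append(
                Residue(res.name, res.seq_num, res.icode, atoms, res.one_letter)
            )
        new_chain = Chain(
            chain_id=chain.chain_id,
            residues=residues,
            molecule_class=chain.molecule_class,
        )
        out.add_chain(new_chain)
    return out


def rotation_about(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cc = 1 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


@pytest.fixture
def dimer_chains():
    """Two 10-residue chains ~4.8 Å apart: a rich, scoreable interface."""
    a = line_chain("A", n_res=10)
    b = line_chain("B", n_res=10, start=(0.0, 4.8, 0.0))
    return a, b
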
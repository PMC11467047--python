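"""Synthetic test complexes with exact ground truth.

Generates idealized poly-helix protein chains, toy nucleic strands, and
hand-placed toy ligands; packs chains so every intended interface has
contacts but no clashes; derives a model structure from the reference by
per-chain rigid perturbation, coordinate noise, and/or chain relabeling.
Includes minimal PDB and mmCIF writers so round-trip tests need no
external files.
"""

from __future__ import annotations

import copy
import gzip as gzip_module
import math
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from ._chem import AMINO_1TO3
from .errors import ComplexQAError
from .io_structures import classify_chain
from .structures import Atom, Chain, FileFormat, MoleculeClass, Residue, Structure

__all__ = [
    "FixtureSpec",
    "RigidPerturbation",
    "make_complex",
    "write_fixture",
    "toy_ligand_chain",
    "TOY_LIGANDS",
]

#: Toy ligand geometries: code -> list of (element, atom name, xyz).
TOY_LIGANDS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    # linear O=C=O
    "CO2": [
        ("C", "C1", (0.0, 0.0, 0.0)),
        ("O", "O1", (1.16, 0.0, 0.0)),
        ("O", "O2", (-1.16, 0.0, 0.0)),
    ],
    # tetrahedral phosphate: 4! = 24 symmetric matches
    "PO4": [
        ("P", "P1", (0.0, 0.0, 0.0)),
        ("O", "O1", (0.889, 0.889, 0.889)),
        ("O", "O2", (0.889, -0.889, -0.889)),
        ("O", "O3", (-0.889, 0.889, -0.889)),
        ("O", "O4", (-0.889, -0.889, 0.889)),
    ],
    # glycerol-like asymmetric chain C3O3
    "GOL": [
        ("C", "C1", (0.0, 0.0, 0.0)),
        ("O", "O1", (0.0, 1.41, 0.0)),
        ("C", "C2", (1.42, -0.55, 0.0)),
        ("O", "O2", (2.30, 0.20, 0.80)),
        ("C", "C3", (1.95, -0.70, -1.42)),
        ("O", "O3", (3.25, -1.20, -1.40)),
    ],
}


@dataclass(frozen=True)
class RigidPerturbation:
    """Rotation (deg, about the chain centroid) plus a translation in Å."""

    angle_deg: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic model/reference pair.

    ``stoichiometry`` strings look like ``"A2"``, ``"A2B1"``, ``"A4"``;
    each letter is a distinct entity (sequence), each count the number of
    copies. Chain ids are assigned A, B, C, ... across all copies in
    order. ``entity_types`` may mark an entity as ``"nucleic"``.
    """

    stoichiometry: str = "A2"
    chain_length: int = 25
    entity_types: dict[str, str] = field(default_factory=dict)
    ligand: Optional[str] = None  # code in TOY_LIGANDS, e.g. "PO4"
    rigid: dict[str, RigidPerturbation] = field(default_factory=dict)
    noise_sigma: dict[str, float] = field(default_factory=dict)
    relabel: Optional[dict[str, str]] = None  # reference id -> model id
    seed: int = 0
    contact_distance: float = 3.5  # packing target for closest approach


# ---------------------------------------------------------------------------
# chain geometry


_PROTEIN_ALPHABET = "ADEFHIKLMNQRSTVWY"  # no G: every residue carries a CB
_NUCLEIC_ALPHABET = ["DA", "DC", "DG", "DT"]


def _entity_sequence(entity: str, length: int) -> list[str]:
    """Deterministic pseudo-random residue names, distinct per entity."""
    rng = np.random.default_rng(1000 + ord(entity))
    picks = rng.integers(0, len(_PROTEIN_ALPHABET), size=length)
    return [AMINO_1TO3[_PROTEIN_ALPHABET[int(i)]] for i in picks]


def _helix_chain(chain_id: str, resnames: list[str]) -> Chain:
    """Idealized alpha-helix-like chain with N, CA, C, O, CB atoms."""
    radius, rise, turn = 2.3, 1.5, math.radians(100.0)
    residues = []
    for i, resname in enumerate(resnames):
        theta = i * turn
        ca = np.array(
            [radius * math.cos(theta), radius * math.sin(theta), rise * i]
        )
        tangent = np.array(
            [-radius * math.sin(theta) * turn,
             radius * math.cos(theta) * turn,
             rise]
        )
        tangent /= np.linalg.norm(tangent)
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        binormal = np.cross(tangent, radial)
        binormal /= np.linalg.norm(binormal)

        def unit(v: np.ndarray) -> np.ndarray:
            return v / np.linalg.norm(v)

        n = ca + 1.45 * unit(-tangent + 0.35 * binormal)
        c = ca + 1.52 * unit(tangent + 0.35 * binormal)
        o = c + 1.23 * unit(binormal - 0.3 * radial)
        cb = ca + 1.53 * radial
        residues.append(
            Residue(
                name=resname,
                seq_num=i + 1,
                atoms=[
                    Atom("N", "N", n),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c),
                    Atom("O", "O", o),
                    Atom("CB", "C", cb),
                ],
            )
        )
    chain = Chain(chain_id=chain_id, residues=residues)
    chain.molecule_class = classify_chain(chain)
    return chain


_NUCLEIC_ATOMS = [
    ("P", "P"), ("OP1", "O"), ("OP2", "O"),
    ("O5'", "O"), ("C5'", "C"), ("C4'", "C"), ("O4'", "O"),
    ("C3'", "C"), ("O3'", "O"), ("C2'", "C"), ("C1'", "C"), ("N1", "N"),
]


def _nucleic_chain(chain_id: str, length: int) -> Chain:
    """Toy single-stranded nucleic helix with the full primed backbone."""
    radius, rise, turn = 7.0, 3.4, math.radians(36.0)
    residues = []
    for i in range(length):
        theta = i * turn
        p = np.array(
            [radius * math.cos(theta), radius * math.sin(theta), rise * i]
        )
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        tangential = np.array([-math.sin(theta), math.cos(theta), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        atoms = [Atom("P", "P", p)]
        atoms.append(Atom("OP1", "O", p + 1.48 * tangential))
        atoms.append(Atom("OP2", "O", p - 1.48 * tangential))
        # sugar trail walks inward and up from the phosphate
        direction = -0.85 * radial + 0.35 * axial + 0.2 * tangential
        direction /= np.linalg.norm(direction)
        side = np.cross(direction, axial)
        side /= np.linalg.norm(side)
        trail = ["O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'", "N1"]
        for k, (name, elem) in enumerate(
            (n, e) for n, e in _NUCLEIC_ATOMS if n in trail
        ):
            wiggle = 0.45 * side * (1 if k % 2 else -1)
            atoms.append(
                Atom(name, elem, p + (k + 1) * 1.35 * direction + wiggle)
            )
        residues.append(
            Residue(
                name=_NUCLEIC_ALPHABET[i % 4],
                seq_num=i + 1,
                atoms=atoms,
            )
        )
    chain = Chain(chain_id=chain_id, residues=residues)
    chain.molecule_class = classify_chain(chain)
    return chain


def toy_ligand_chain(code: str, chain_id: str = "L") -> Chain:
    if code not in TOY_LIGANDS:
        raise ComplexQAError(
            f"unknown toy ligand {code!r}; choose from {sorted(TOY_LIGANDS)}"
        )
    atoms = [
        Atom(name, element, np.array(xyz))
        for element, name, xyz in TOY_LIGANDS[code]
    ]
    chain = Chain(
        chain_id=chain_id,
        residues=[Residue(name=code, seq_num=1, atoms=atoms)],
        molecule_class=MoleculeClass.SMALL_MOLECULE,
    )
    return chain


# ---------------------------------------------------------------------------
# packing


def _all_coords(chain: Chain) -> np.ndarray:
    return np.array([a.coords for r in chain.residues for a in r.atoms])


def _translate_chain(chain: Chain, shift: np.ndarray) -> Chain:
    return _transform_chain(chain, np.eye(3), np.asarray(shift, float))


def _transform_chain(
    chain: Chain, rotation: np.ndarray, translation: np.ndarray
) -> Chain:
    new_residues = []
    for res in chain.residues:
        new_atoms = [
            Atom(a.name, a.element, rotation @ a.coords + translation)
            for a in res.atoms
        ]
        new_residues.append(
            Residue(res.name, res.seq_num, res.icode, new_atoms, res.one_letter)
        )
    return Chain(
        chain_id=chain.chain_id,
        residues=new_residues,
        molecule_class=chain.molecule_class,
    )


def _min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    tree = cKDTree(coords_b)
    d, _ = tree.query(coords_a, k=1)
    return float(np.min(d))


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    cc = 1 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


def _pack_ring(template: Chain, ids: list[str], target: float) -> list[Chain]:
    """Place k rotated copies of a chain on a ring so neighbours touch.

    The ring radius is found by bisection on the minimum inter-chain
    distance, which grows monotonically with the radius once the copies
    no longer overlap.
    """
    k = len(ids)
    coords = _all_coords(template)
    center = coords.mean(axis=0)

    def place(offset: float) -> list[np.ndarray]:
        placed = []
        for i in range(k):
            rot = _rotation_matrix(np.array([0.0, 0.0, 1.0]), 2 * math.pi * i / k)
            placed.append(
                (coords - center + np.array([offset, 0.0, 0.0])) @ rot.T
            )
        return placed

    def min_gap(offset: float) -> float:
        placed = place(offset)
        return min(
            _min_distance(placed[i], placed[j])
            for i in range(k)
            for j in range(i + 1, k)
        )

    lo, hi = 0.0, 300.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) < target:
            lo = mid
        else:
            hi = mid
    offset = hi
    chains = []
    for i, cid in enumerate(ids):
        rot = _rotation_matrix(np.array([0.0, 0.0, 1.0]), 2 * math.pi * i / k)
        shifted = _translate_chain(template, -center + np.array([offset, 0, 0]))
        chain = _transform_chain(shifted, rot, np.zeros(3))
        chain.chain_id = cid
        chains.append(chain)
    return chains


def _pack_against(
    chain: Chain,
    placed: list[Chain],
    direction: np.ndarray,
    target: float,
) -> Chain:
    """Slide a chain along ``direction`` until it just touches ``placed``."""
    placed_coords = np.vstack([_all_coords(c) for c in placed])
    coords = _all_coords(chain)
    center = coords.mean(axis=0)
    anchor = placed_coords.mean(axis=0)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)

    def gap(t: float) -> float:
        shift = anchor + t * direction - center
        return _min_distance(coords + shift, placed_coords)

    lo, hi = 0.0, 300.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) < target:
            lo = mid
        else:
            hi = mid
    shift = anchor + hi * direction - center
    return _translate_chain(chain, shift)


# ---------------------------------------------------------------------------
# complex assembly


_STOICH_RE = re.compile(r"([A-Z])(\d+)")


def _parse_stoichiometry(stoich: str) -> list[tuple[str, int]]:
    entities = _STOICH_RE.findall(stoich)
    if not entities or "".join(f"{e}{n}" for e, n in entities) != stoich:
        raise ComplexQAError(f"cannot parse stoichiometry {stoich!r}")
    return [(e, int(n)) for e, n in entities]


def make_complex(
    spec: FixtureSpec,
) -> tuple[Structure, Structure, dict]:
    """Build a (model, reference, ground_truth) triple from a spec.

    The reference is assembled from idealized chains; the model applies
    the requested perturbations and relabeling. ``ground_truth`` holds
    the model->reference chain mapping and the perturbations used.
    """
    entities = _parse_stoichiometry(spec.stoichiometry)
    n_chains = sum(n for _, n in entities)
    chain_ids = [chr(ord("A") + i) for i in range(n_chains)]

    reference = Structure(source_path="<fixture>", format=None)
    idx = 0
    first_entity, first_count = entities[0]
    for entity, count in entities:
        ids = chain_ids[idx: idx + count]
        idx += count
        etype = spec.entity_types.get(entity, "protein")
        if etype == "nucleic":
            template = _nucleic_chain(ids[0], spec.chain_length)
        else:
            template = _helix_chain(
                ids[0], _entity_sequence(entity, spec.chain_length)
            )
        if entity == first_entity:
            if count == 1:
                template.chain_id = ids[0]
                for cid, chain in [(ids[0], template)]:
                    reference.add_chain(chain)
            else:
                for chain in _pack_ring(template, ids, spec.contact_distance):
                    reference.add_chain(chain)
        else:
            # later entities lean against everything placed so far
            for j, cid in enumerate(ids):
                direction = _rotation_matrix(
                    np.array([0.0, 0.0, 1.0]), j * 2.1
                ) @ np.array([0.0, 1.0, 0.0])
                chain = _pack_against(
                    template,
                    list(reference),
                    direction,
                    spec.contact_distance,
                )
                chain.chain_id = cid
                reference.add_chain(chain)

    if spec.ligand is not None:
        lig = toy_ligand_chain(spec.ligand, chain_id=chain_ids[-1])
        lig_id = chr(ord("A") + n_chains)
        lig.chain_id = lig_id
        # slide outward through the first chain's centroid so the ligand
        # touches that chain and nothing else
        all_coords = np.vstack([_all_coords(c) for c in reference])
        first_centroid = _all_coords(reference[chain_ids[0]]).mean(axis=0)
        direction = first_centroid - all_coords.mean(axis=0)
        if np.linalg.norm(direction) < 1e-6:
            direction = np.array([1.0, 0.0, 0.2])
        placed = _pack_against(
            lig,
            list(reference),
            direction,
            max(spec.contact_distance - 0.4, 3.2),
        )
        placed.chain_id = lig_id
        reference.add_chain(placed)
        chain_ids.append(lig_id)

    # sanity: self-avoiding and in contact
    ref_chains = list(reference)
    for i, ca in enumerate(ref_chains):
        for cb in ref_chains[i + 1:]:
            gap = _min_distance(_all_coords(ca), _all_coords(cb))
            if gap < 2.5:
                raise ComplexQAError(
                    f"fixture chains {ca.chain_id}/{cb.chain_id} clash "
                    f"(min distance {gap:.2f} Å)"
                )

    # model: perturb + relabel
    rng = np.random.default_rng(spec.seed)
    model = Structure(source_path="<fixture-model>", format=None)
    relabel = spec.relabel or {}
    model_chains = []
    for chain in reference:
        cid = chain.chain_id
        perturbed = copy.deepcopy(chain)
        perturbed.__dict__.pop("_heavy_cache", None)
        perturbed.__dict__.pop("_key_idx", None)
        if cid in spec.rigid:
            p = spec.rigid[cid]
            rot = _rotation_matrix(
                np.array(p.axis), math.radians(p.angle_deg)
            )
            coords = _all_coords(perturbed)
            center = coords.mean(axis=0)
            shift = center - rot @ center + np.array(p.translation)
            perturbed = _transform_chain(perturbed, rot, shift)
        sigma = spec.noise_sigma.get(cid, 0.0)
        if sigma > 0:
            for res in perturbed.residues:
                noisy = []
                for atom in res.atoms:
                    noisy.append(
                        Atom(
                            atom.name,
                            atom.element,
                            atom.coords + rng.normal(0.0, sigma, 3),
                        )
                    )
                res.atoms = noisy
        new_id = relabel.get(cid, cid)
        perturbed.chain_id = new_id
        model_chains.append(perturbed)
    for chain in sorted(model_chains, key=lambda c: c.chain_id):
        model.add_chain(chain)

    ground_truth = {
        "mapping": {relabel.get(cid, cid): cid for cid in chain_ids},
        "rigid": dict(spec.rigid),
        "noise_sigma": dict(spec.noise_sigma),
    }
    return model, reference, ground_truth


# ---------------------------------------------------------------------------
# writers


def _pdb_atom_line(
    serial: int, atom: Atom, res: Residue, chain_id: str, hetatm: bool
) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    record = "HETATM" if hetatm else "ATOM  "
    x, y, z = atom.coords
    return (
        f"{record}{serial:>5} {name:<4} {res.name:>3} {chain_id:1}"
        f"{res.seq_num:>4}{res.icode or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2}"
    )


def _render_pdb(structure: Structure) -> str:
    lines = []
    serial = 1
    for chain in structure:
        if len(chain.chain_id) != 1:
            raise ComplexQAError(
                f"PDB format needs single-character chain ids, got "
                f"{chain.chain_id!r}"
            )
        hetatm = chain.molecule_class is MoleculeClass.SMALL_MOLECULE
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(
                    _pdb_atom_line(serial, atom, res, chain.chain_id, hetatm)
                )
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_MMCIF_HEADER = """\
data_fixture
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
"""


def _render_mmcif(structure: Structure) -> str:
    rows = []
    serial = 1
    for entity_id, chain in enumerate(structure, start=1):
        hetatm = chain.molecule_class is MoleculeClass.SMALL_MOLECULE
        group = "HETATM" if hetatm else "ATOM"
        for res in chain.residues:
            for atom in res.atoms:
                x, y, z = atom.coords
                rows.append(
                    " ".join(
                        [
                            group,
                            str(serial),
                            atom.element,
                            f'"{atom.name}"',
                            ".",
                            res.name,
                            chain.chain_id,
                            str(entity_id),
                            "." if hetatm else str(res.seq_num),
                            res.icode or "?",
                            f"{x:.3f}",
                            f"{y:.3f}",
                            f"{z:.3f}",
                            "1.00",
                            "0.00",
                            str(res.seq_num),
                            res.name,
                            chain.chain_id,
                            f'"{atom.name}"',
                            "1",
                        ]
                    )
                )
                serial += 1
    return _MMCIF_HEADER + "\n".join(rows) + "\n#\n"


def write_fixture(
    structure: Structure,
    path,
    format: FileFormat = FileFormat.PDB,
    gzip: bool = False,
) -> str:
    """Write a structure as PDB or mmCIF text, optionally gzipped.

    Output is deterministic (no timestamps) so identical structures
    produce byte-identical files.
    """
    path = str(path)
    text = (
        _render_pdb(structure)
        if format is FileFormat.PDB
        else _render_mmcif(structure)
    )
    if gzip:
        # pin mtime and omit the filename header for reproducible bytes
        with open(path, "wb") as raw:
            with gzip_module.GzipFile(
                filename="", mode="wb", fileobj=raw, mtime=0
            ) as fh:
                fh.write(text.encode("utf-8"))
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return path
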
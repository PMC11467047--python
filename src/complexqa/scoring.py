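"""Interface quality measures for one model/reference chain pair.

Implements the contact, RMSD and combined score calculations:

* ``find_contacts`` — residue contacts from heavy-atom distances
* ``compute_fnat`` — fraction of native contacts reproduced by the model
* ``superpose`` — least-squares (Kabsch) rigid superposition
* ``define_interface_residues`` / ``compute_irmsd`` — interface backbone RMSD
* ``compute_lrmsd`` — ligand-chain backbone RMSD after receptor superposition
* ``count_clashes`` — inter-chain heavy-atom pairs below a physical minimum
* ``compute_dockq`` — the combined [0, 1] score
* ``score_interface`` — orchestration into one :class:`InterfaceResult`

Distance queries run on k-d trees but are exact: results equal brute-force
all-pairs enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .constants import CAPRI_CLASSES, DEFAULT_CONSTANTS, ScoringConstants
from .correspondence import ResidueCorrespondence
from .errors import InsufficientAtomsError, NoNativeInterfaceError
from .structures import Chain, MoleculeClass, Residue

__all__ = [
    "ContactSet",
    "InterfaceResult",
    "find_contacts",
    "compute_fnat",
    "superpose",
    "define_interface_residues",
    "compute_irmsd",
    "compute_lrmsd",
    "count_clashes",
    "compute_dockq",
    "classify_capri",
    "score_interface",
]

ResidueKey = tuple[int, str]
#: contacts are stored as frozensets of (key_in_A, key_in_B) pairs
ContactSet = frozenset


def backbone_atom_names(molecule_class: MoleculeClass,
                        constants: ScoringConstants) -> frozenset:
    if molecule_class.is_amino:
        return constants.protein_backbone
    return constants.nucleic_backbone


def find_contacts(chain_a: Chain, chain_b: Chain, cutoff: float) -> ContactSet:
    """Residue pairs with at least one heavy-atom pair within ``cutoff`` Å."""
    coords_a, keys_a = chain_a.heavy_coords()
    coords_b, keys_b = chain_b.heavy_coords()
    if len(coords_a) == 0 or len(coords_b) == 0:
        return frozenset()
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    contacts = set()
    for ia, neighbours in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        for ib in neighbours:
            contacts.add((keys_a[ia], keys_b[ib]))
    return frozenset(contacts)


def compute_fnat(
    model_contacts: ContactSet,
    native_contacts: ContactSet,
    corr_a: ResidueCorrespondence,
    corr_b: ResidueCorrespondence,
) -> tuple[float, float, int, int, int]:
    """Fraction of native contacts reproduced by the model.

    Model contacts are translated into reference residue keys through the
    correspondences; a model contact over unmapped residues has no native
    counterpart and counts as non-native.

    Returns ``(fnat, fnonnat, n_correct, n_native, n_model)``.
    """
    if not native_contacts:
        raise NoNativeInterfaceError(
            "reference chain pair has no contacts; not a scoreable interface"
        )
    translated = set()
    n_untranslatable = 0
    for key_a, key_b in model_contacts:
        ref_a = corr_a.model_to_ref.get(key_a)
        ref_b = corr_b.model_to_ref.get(key_b)
        if ref_a is None or ref_b is None:
            n_untranslatable += 1
        else:
            translated.add((ref_a, ref_b))
    correct = translated & set(native_contacts)
    fnat = len(correct) / len(native_contacts)
    n_model = len(model_contacts)
    fnonnat = (
        (n_model - len(correct)) / n_model if n_model else 0.0
    )
    return fnat, fnonnat, len(correct), len(native_contacts), n_model


def superpose(
    coords_ref: np.ndarray, coords_mov: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_mov`` onto ``coords_ref``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1) such that ``coords_mov @ rotation.T + translation``
    minimizes the RMS distance to ``coords_ref``.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mov = np.asarray(coords_mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise InsufficientAtomsError(
            f"coordinate shapes differ or are not N×3: {ref.shape} vs {mov.shape}"
        )
    n = ref.shape[0]
    if n < 3:
        raise InsufficientAtomsError(
            f"need at least 3 paired points for superposition, got {n}"
        )
    centroid_ref = ref.mean(axis=0)
    centroid_mov = mov.mean(axis=0)
    p = ref - centroid_ref
    q = mov - centroid_mov
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = centroid_ref - rotation @ centroid_mov
    moved = q @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))
    return rotation, translation, rmsd


def _cb_or_ca(residue: Residue) -> Optional[np.ndarray]:
    atom = residue.atom("CB") or residue.atom("CA")
    return atom.coords if atom is not None else None


def define_interface_residues(
    ref_chain_a: Chain,
    ref_chain_b: Chain,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Interface residues of a reference chain pair.

    All-heavy-atom rule within ``interface_cutoff`` for protein/nucleic
    pairs; Cβ–Cβ within ``interface_cutoff_peptide_cb`` (Cα for glycine)
    when the pair involves a peptide and both chains are amino polymers.
    """
    peptide_pair = (
        (ref_chain_a.molecule_class is MoleculeClass.PEPTIDE
         or ref_chain_b.molecule_class is MoleculeClass.PEPTIDE)
        and ref_chain_a.molecule_class.is_amino
        and ref_chain_b.molecule_class.is_amino
    )
    set_a: set[ResidueKey] = set()
    set_b: set[ResidueKey] = set()
    if peptide_pair:
        cutoff = constants.interface_cutoff_peptide_cb
        pts_a = [(r.key, _cb_or_ca(r)) for r in ref_chain_a.residues]
        pts_b = [(r.key, _cb_or_ca(r)) for r in ref_chain_b.residues]
        pts_a = [(k, c) for k, c in pts_a if c is not None]
        pts_b = [(k, c) for k, c in pts_b if c is not None]
        if not pts_a or not pts_b:
            return set_a, set_b
        tree_b = cKDTree(np.array([c for _, c in pts_b]))
        for key_a, coord in pts_a:
            for ib in tree_b.query_ball_point(coord, cutoff):
                set_a.add(key_a)
                set_b.add(pts_b[ib][0])
        return set_a, set_b
    for key_a, key_b in find_contacts(
        ref_chain_a, ref_chain_b, constants.interface_cutoff
    ):
        set_a.add(key_a)
        set_b.add(key_b)
    return set_a, set_b


def _gather_paired_backbone(
    ref_chain: Chain,
    corr: ResidueCorrespondence,
    residue_keys,
    atom_names: frozenset,
) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """Paired (ref, model) backbone coordinates for the given ref residues.

    Atoms present in only one of the two structures are skipped; the count
    of skipped atoms is returned alongside.
    """
    ref_coords: list[np.ndarray] = []
    mov_coords: list[np.ndarray] = []
    n_skipped = 0
    for key in residue_keys:
        ref_res = ref_chain.residue_by_key(key)
        model_res = corr.ref_to_model_residue.get(key)
        if model_res is None:
            continue
        for atom_name in sorted(atom_names):
            ref_atom = ref_res.atom(atom_name)
            model_atom = model_res.atom(atom_name)
            if ref_atom is None and model_atom is None:
                continue
            if ref_atom is None or model_atom is None:
                n_skipped += 1
                continue
            ref_coords.append(ref_atom.coords)
            mov_coords.append(model_atom.coords)
    return ref_coords, mov_coords, n_skipped


def compute_irmsd(
    ref_chain_a: Chain,
    ref_chain_b: Chain,
    corr_a: ResidueCorrespondence,
    corr_b: ResidueCorrespondence,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> float:
    """Backbone RMSD of the reference-defined interface residues.

    Superposition and evaluation both run over the backbone atoms of
    interface residues that are paired and present in both structures.
    """
    iface_a, iface_b = define_interface_residues(
        ref_chain_a, ref_chain_b, constants
    )
    ref_coords: list[np.ndarray] = []
    mov_coords: list[np.ndarray] = []
    n_skipped = 0
    for chain, corr, keys in (
        (ref_chain_a, corr_a, iface_a),
        (ref_chain_b, corr_b, iface_b),
    ):
        names = backbone_atom_names(chain.molecule_class, constants)
        r, m, skipped = _gather_paired_backbone(chain, corr, sorted(keys), names)
        ref_coords.extend(r)
        mov_coords.extend(m)
        n_skipped += skipped
    if len(ref_coords) < 3:
        raise InsufficientAtomsError(
            "fewer than 3 paired interface backbone atoms for iRMSD "
            f"({ref_chain_a.chain_id}:{ref_chain_b.chain_id})"
        )
    if n_skipped:
        warnings.warn(
            f"iRMSD skipped {n_skipped} backbone atoms missing from one "
            "structure",
            stacklevel=2,
        )
    _, _, rmsd = superpose(np.array(ref_coords), np.array(mov_coords))
    return rmsd


def compute_lrmsd(
    ref_chain_a: Chain,
    ref_chain_b: Chain,
    corr_a: ResidueCorrespondence,
    corr_b: ResidueCorrespondence,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> tuple[float, str, str]:
    """Ligand-chain backbone RMSD after superposing on the receptor.

    The receptor is the reference chain with more residues; on a tie the
    first of the pair (reference chain order) is the receptor. Returns
    ``(lrmsd, receptor_chain_id, ligand_chain_id)``.
    """
    if len(ref_chain_b.residues) > len(ref_chain_a.residues):
        receptor, ligand = ref_chain_b, ref_chain_a
        corr_receptor, corr_ligand = corr_b, corr_a
    else:
        receptor, ligand = ref_chain_a, ref_chain_b
        corr_receptor, corr_ligand = corr_a, corr_b

    rec_names = backbone_atom_names(receptor.molecule_class, constants)
    rec_ref, rec_mov, _ = _gather_paired_backbone(
        receptor, corr_receptor, [r.key for r in receptor.residues], rec_names
    )
    if len(rec_ref) < 3:
        raise InsufficientAtomsError(
            f"fewer than 3 paired receptor backbone atoms "
            f"({receptor.chain_id})"
        )
    rotation, translation, _ = superpose(np.array(rec_ref), np.array(rec_mov))

    lig_names = backbone_atom_names(ligand.molecule_class, constants)
    lig_ref, lig_mov, _ = _gather_paired_backbone(
        ligand, corr_ligand, [r.key for r in ligand.residues], lig_names
    )
    if not lig_ref:
        raise InsufficientAtomsError(
            f"no paired ligand backbone atoms ({ligand.chain_id})"
        )
    moved = np.array(lig_mov) @ rotation.T + translation
    diff = moved - np.array(lig_ref)
    lrmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return lrmsd, receptor.chain_id, ligand.chain_id


def count_clashes(
    model_chain_a: Chain,
    model_chain_b: Chain,
    clash_cutoff: float = DEFAULT_CONSTANTS.clash_cutoff,
) -> int:
    """Number of inter-chain heavy-atom pairs strictly below the cutoff."""
    coords_a, _ = model_chain_a.heavy_coords()
    coords_b, _ = model_chain_b.heavy_coords()
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    n = 0
    for ia, neighbours in enumerate(
        tree_a.query_ball_tree(tree_b, clash_cutoff)
    ):
        for ib in neighbours:
            if np.linalg.norm(coords_a[ia] - coords_b[ib]) < clash_cutoff:
                n += 1
    return n


def compute_dockq(
    fnat: float,
    irmsd: float,
    lrmsd: float,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> float:
    """Combined [0, 1] quality score from fnat and the two scaled RMSDs."""
    return (
        fnat
        + 1.0 / (1.0 + (irmsd / constants.a) ** 2)
        + 1.0 / (1.0 + (lrmsd / constants.b) ** 2)
    ) / 3.0


def classify_capri(
    dockq: float, constants: ScoringConstants = DEFAULT_CONSTANTS
) -> str:
    """CAPRI quality class for a DockQ value (half-open boundaries)."""
    if dockq < constants.capri_acceptable:
        return CAPRI_CLASSES[0]
    if dockq < constants.capri_medium:
        return CAPRI_CLASSES[1]
    if dockq < constants.capri_high:
        return CAPRI_CLASSES[2]
    return CAPRI_CLASSES[3]


@dataclass
class InterfaceResult:
    """All quality measures for one polymer-polymer interface."""

    fnat: float
    fnonnat: float
    irmsd: float
    lrmsd: float
    dockq: float
    clashes: int
    native_contacts: int
    model_contacts: int
    correct_contacts: int
    receptor_chain: str
    ligand_chain: str
    capri_class: str
    model_pair: tuple[str, str] = ("", "")
    ref_pair: tuple[str, str] = ("", "")

    def to_dict(self) -> dict:
        return {
            "kind": "polymer",
            "model_pair": list(self.model_pair),
            "ref_pair": list(self.ref_pair),
            "fnat": self.fnat,
            "fnonnat": self.fnonnat,
            "irmsd": self.irmsd,
            "lrmsd": self.lrmsd,
            "dockq": self.dockq,
            "capri_class": self.capri_class,
            "clashes": self.clashes,
            "native_contacts": self.native_contacts,
            "model_contacts": self.model_contacts,
            "correct_contacts": self.correct_contacts,
            "receptor_chain": self.receptor_chain,
            "ligand_chain": self.ligand_chain,
        }


def score_interface(
    model_chain_a: Chain,
    model_chain_b: Chain,
    ref_chain_a: Chain,
    ref_chain_b: Chain,
    corr_a: ResidueCorrespondence,
    corr_b: ResidueCorrespondence,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> InterfaceResult:
    """Score one model chain pair against one reference chain pair.

    ``corr_a`` pairs ``model_chain_a`` with ``ref_chain_a`` and likewise
    for ``corr_b``. Raises :class:`NoNativeInterfaceError` when the
    reference pair has no contacts.
    """
    peptide = (
        ref_chain_a.molecule_class is MoleculeClass.PEPTIDE
        or ref_chain_b.molecule_class is MoleculeClass.PEPTIDE
    )
    cutoff = (
        constants.contact_cutoff_peptide if peptide else constants.contact_cutoff
    )
    native = find_contacts(ref_chain_a, ref_chain_b, cutoff)
    if not native:
        raise NoNativeInterfaceError(
            f"reference chains {ref_chain_a.chain_id}:{ref_chain_b.chain_id} "
            "share no contacts"
        )
    model = find_contacts(model_chain_a, model_chain_b, cutoff)
    fnat, fnonnat, n_correct, n_native, n_model = compute_fnat(
        model, native, corr_a, corr_b
    )
    irmsd = compute_irmsd(ref_chain_a, ref_chain_b, corr_a, corr_b, constants)
    lrmsd, receptor_id, ligand_id = compute_lrmsd(
        ref_chain_a, ref_chain_b, corr_a, corr_b, constants
    )
    clashes = count_clashes(
        model_chain_a, model_chain_b, constants.clash_cutoff
    )
    dockq = compute_dockq(fnat, irmsd, lrmsd, constants)
    return InterfaceResult(
        fnat=fnat,
        fnonnat=fnonnat,
        irmsd=irmsd,
        lrmsd=lrmsd,
        dockq=dockq,
        clashes=clashes,
        native_contacts=n_native,
        model_contacts=n_model,
        correct_contacts=n_correct,
        receptor_chain=receptor_id,
        ligand_chain=ligand_id,
        capri_class=classify_capri(dockq, constants),
        model_pair=(model_chain_a.chain_id, model_chain_b.chain_id),
        ref_pair=(ref_chain_a.chain_id, ref_chain_b.chain_id),
    )
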
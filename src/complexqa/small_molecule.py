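"""Small-molecule ligand scoring.

Ligands are compared as element-labeled molecular graphs whose edges are
perceived from covalent radii. All label-preserving graph isomorphisms
between model and reference ligand are enumerated and the pocket-aligned
heavy-atom RMSD is minimized over them, so symmetric molecules (swapped
equivalent atoms) score correctly. Only the pocket-aligned LRMSD is
reported for small molecules — no fnat, iRMSD, or DockQ.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .constants import COVALENT_RADII, DEFAULT_CONSTANTS, ScoringConstants
from .correspondence import ResidueCorrespondence
from .errors import (
    ComplexQAError,
    EmptyPocketError,
    InsufficientAtomsError,
    MatchCapExceededError,
    NonIsomorphicLigandsError,
)
from .scoring import _gather_paired_backbone, backbone_atom_names, superpose
from .structures import Chain

__all__ = [
    "MolecularGraph",
    "AtomMapping",
    "LigandResult",
    "build_molecular_graph",
    "enumerate_matches",
    "pocket_aligned_lrmsd",
]


@dataclass
class MolecularGraph:
    """Element-labeled heavy-atom graph of one ligand."""

    graph: nx.Graph  # nodes: atom indices with 'element' attr
    coords: np.ndarray  # (n_atoms, 3)
    atom_names: list[str]

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    def element(self, index: int) -> str:
        return self.graph.nodes[index]["element"]


@dataclass(frozen=True)
class AtomMapping:
    """Bijection model atom index -> reference atom index."""

    pairs: tuple[tuple[int, int], ...]

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class LigandResult:
    """Pocket-aligned LRMSD record for one receptor/ligand interface."""

    lrmsd: float
    atom_mapping: AtomMapping
    n_mappings_tried: int
    receptor_chain: str
    ligand_chain: str
    model_pair: tuple[str, str] = ("", "")
    ref_pair: tuple[str, str] = ("", "")
    clashes: int = 0

    def to_dict(self) -> dict:
        return {
            "kind": "small_molecule",
            "model_pair": list(self.model_pair),
            "ref_pair": list(self.ref_pair),
            "lrmsd": self.lrmsd,
            "n_mappings_tried": self.n_mappings_tried,
            "receptor_chain": self.receptor_chain,
            "ligand_chain": self.ligand_chain,
            "clashes": self.clashes,
        }


def build_molecular_graph(ligand: Chain) -> MolecularGraph:
    """Perceive covalent bonds of a ligand from inter-atomic distances.

    An edge joins atoms *i*, *j* when their distance is at most the sum of
    their covalent radii plus the configured tolerance. Hydrogens were
    already removed at parse time.
    """
    atoms = [a for res in ligand.residues for a in res.heavy_atoms]
    if not atoms:
        raise ComplexQAError(
            f"ligand chain {ligand.chain_id!r} has no heavy atoms"
        )
    radii = []
    for atom in atoms:
        r = COVALENT_RADII.get(atom.element.upper())
        if r is None:
            raise ComplexQAError(
                f"no covalent radius for element {atom.element!r} "
                f"(atom {atom.name} in chain {ligand.chain_id})"
            )
        radii.append(r)
    coords = np.array([a.coords for a in atoms])
    tol = DEFAULT_CONSTANTS.covalent_tolerance
    graph = nx.Graph()
    for i, atom in enumerate(atoms):
        graph.add_node(i, element=atom.element.upper())
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            cutoff = radii[i] + radii[j] + tol
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                graph.add_edge(i, j)
    return MolecularGraph(
        graph=graph, coords=coords, atom_names=[a.name for a in atoms]
    )


def enumerate_matches(
    model_graph: MolecularGraph,
    ref_graph: MolecularGraph,
    match_cap: int = DEFAULT_CONSTANTS.match_cap,
) -> list[AtomMapping]:
    """All element-preserving isomorphisms model graph -> reference graph.

    Returns an empty list for non-isomorphic graphs; raises
    :class:`MatchCapExceededError` beyond ``match_cap`` matches.
    """
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        model_graph.graph,
        ref_graph.graph,
        node_match=lambda n1, n2: n1["element"] == n2["element"],
    )
    mappings = []
    for iso in matcher.isomorphisms_iter():
        mappings.append(AtomMapping(pairs=tuple(sorted(iso.items()))))
        if len(mappings) > match_cap:
            raise MatchCapExceededError(
                f"more than {match_cap} ligand atom matches; supply an "
                "explicit mapping"
            )
    return sorted(mappings, key=lambda m: m.pairs)


def _pocket_residue_keys(
    ref_receptor: Chain, ref_ligand: Chain, cutoff: float
) -> list:
    lig_coords, _ = ref_ligand.heavy_coords()
    rec_coords, rec_keys = ref_receptor.heavy_coords()
    if len(lig_coords) == 0 or len(rec_coords) == 0:
        return []
    tree = cKDTree(lig_coords)
    keys = set()
    for i, neighbours in enumerate(
        cKDTree(rec_coords).query_ball_tree(tree, cutoff)
    ):
        if neighbours:
            keys.add(rec_keys[i])
    return sorted(keys)


def pocket_aligned_lrmsd(
    model_receptor: Chain,
    ref_receptor: Chain,
    model_ligand: Chain,
    ref_ligand: Chain,
    receptor_corr: ResidueCorrespondence,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> LigandResult:
    """Minimum all-heavy-atom ligand RMSD after pocket superposition.

    The pocket is the set of reference receptor residues with any heavy
    atom within ``interface_cutoff`` of the reference ligand; the model is
    superposed on the reference over the pocket backbone atoms, then the
    ligand RMSD is minimized over all enumerated atom mappings.
    """
    model_graph = build_molecular_graph(model_ligand)
    ref_graph = build_molecular_graph(ref_ligand)
    mappings = enumerate_matches(model_graph, ref_graph, constants.match_cap)
    if not mappings:
        raise NonIsomorphicLigandsError(
            f"model ligand {model_ligand.chain_id!r} does not match "
            f"reference ligand {ref_ligand.chain_id!r} (elements or "
            "connectivity differ)"
        )

    pocket_keys = _pocket_residue_keys(
        ref_receptor, ref_ligand, constants.interface_cutoff
    )
    if not pocket_keys:
        raise EmptyPocketError(
            f"no receptor residues within {constants.interface_cutoff} Å of "
            f"reference ligand {ref_ligand.chain_id!r}"
        )
    names = backbone_atom_names(ref_receptor.molecule_class, constants)
    ref_bb, mov_bb, _ = _gather_paired_backbone(
        ref_receptor, receptor_corr, pocket_keys, names
    )
    if len(ref_bb) < 3:
        raise InsufficientAtomsError(
            "fewer than 3 paired pocket backbone atoms for ligand "
            f"{ref_ligand.chain_id!r}"
        )
    rotation, translation, _ = superpose(np.array(ref_bb), np.array(mov_bb))
    moved = model_graph.coords @ rotation.T + translation

    best_rmsd = np.inf
    best_mapping = mappings[0]
    for mapping in mappings:
        model_idx = [m for m, _ in mapping.pairs]
        ref_idx = [r for _, r in mapping.pairs]
        diff = moved[model_idx] - ref_graph.coords[ref_idx]
        rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
        if rmsd < best_rmsd:
            best_rmsd = rmsd
            best_mapping = mapping
    return LigandResult(
        lrmsd=best_rmsd,
        atom_mapping=best_mapping,
        n_mappings_tried=len(mappings),
        receptor_chain=ref_receptor.chain_id,
        ligand_chain=ref_ligand.chain_id,
        model_pair=(model_receptor.chain_id, model_ligand.chain_id),
        ref_pair=(ref_receptor.chain_id, ref_ligand.chain_id),
    )
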
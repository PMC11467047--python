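"""Residue correspondence between model and reference chains.

Equivalent residues are paired either by global sequence alignment
(default) or by author residue numbering; chains are grouped into
equivalence classes ahead of the chain-mapping search.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align

from .constants import DEFAULT_CONSTANTS
from .errors import CorrespondenceError
from .io_structures import extract_sequence
from .structures import Chain, MoleculeClass, Residue, Structure

__all__ = [
    "MappingMode",
    "ResidueCorrespondence",
    "ChainGroup",
    "align_sequences",
    "alignment_identity",
    "map_residues",
    "group_equivalent_chains",
]


class MappingMode(enum.Enum):
    ALIGNMENT = "alignment"
    NUMBERING = "numbering"


@dataclass
class ResidueCorrespondence:
    """One-to-one pairing of model and reference residues for a chain pair."""

    pairs: list[tuple[Residue, Residue]]
    coverage: float
    mode: MappingMode
    n_mismatch: int = 0
    model_chain_id: str = ""
    ref_chain_id: str = ""
    #: model residue key -> reference residue key
    model_to_ref: dict[tuple[int, str], tuple[int, str]] = field(
        default_factory=dict
    )
    #: reference residue key -> model residue
    ref_to_model_residue: dict[tuple[int, str], Residue] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.model_to_ref:
            self.model_to_ref = {m.key: r.key for m, r in self.pairs}
            self.ref_to_model_residue = {r.key: m for m, r in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ChainGroup:
    """Chains of one structure that are copies of the same subunit."""

    member_chain_ids: list[str]
    representative_sequence: str  # sequence, or component code for ligands
    molecule_class: MoleculeClass

    def __len__(self) -> int:
        return len(self.member_chain_ids)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    # Identity-style scoring; model and reference sequences are near
    # identical so anything reasonable yields the same pairing. End gaps
    # are free so truncated termini are not forced into internal gaps.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.end_gap_score = 0.0
    return aligner


def align_sequences(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Globally align two sequences; returns the gapped aligned strings."""
    if not seq_a or not seq_b:
        raise CorrespondenceError("cannot align empty sequences")
    alignment = _aligner().align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1])


def alignment_identity(aligned_a: str, aligned_b: str) -> float:
    """Fraction of identical residues over aligned (gap-free) columns."""
    cols = [
        (a, b)
        for a, b in zip(aligned_a, aligned_b)
        if a != "-" and b != "-"
    ]
    if not cols:
        return 0.0
    return sum(a == b for a, b in cols) / len(cols)


def map_residues(
    model_chain: Chain,
    ref_chain: Chain,
    mode: MappingMode = MappingMode.ALIGNMENT,
) -> ResidueCorrespondence:
    """Pair equivalent residues of a model chain and a reference chain.

    ALIGNMENT mode pairs residues at aligned non-gap columns of the global
    sequence alignment (mismatching residues are still paired and counted);
    NUMBERING mode pairs residues sharing author number + insertion code.
    """
    seq_m = extract_sequence(model_chain)
    seq_r = extract_sequence(ref_chain)
    pairs: list[tuple[Residue, Residue]] = []
    n_mismatch = 0
    if mode is MappingMode.NUMBERING:
        ref_index = {r.key: i for i, r in enumerate(ref_chain.residues)}
        for im, m_res in enumerate(model_chain.residues):
            ir = ref_index.get(m_res.key)
            if ir is not None:
                pairs.append((m_res, ref_chain.residues[ir]))
                n_mismatch += seq_m[im] != seq_r[ir]
    else:
        aligned_m, aligned_r = align_sequences(seq_m, seq_r)
        im = ir = 0
        for cm, cr in zip(aligned_m, aligned_r):
            if cm != "-" and cr != "-":
                pairs.append(
                    (model_chain.residues[im], ref_chain.residues[ir])
                )
                n_mismatch += cm != cr
            if cm != "-":
                im += 1
            if cr != "-":
                ir += 1
    if not pairs:
        raise CorrespondenceError(
            f"no residues could be paired between model chain "
            f"{model_chain.chain_id!r} and reference chain "
            f"{ref_chain.chain_id!r} ({mode.value} mode)"
        )
    return ResidueCorrespondence(
        pairs=pairs,
        coverage=len(pairs) / len(ref_chain.residues),
        mode=mode,
        n_mismatch=n_mismatch,
        model_chain_id=model_chain.chain_id,
        ref_chain_id=ref_chain.chain_id,
    )


def _chains_equivalent(
    chain: Chain, group: ChainGroup, identity_threshold: float
) -> bool:
    if chain.molecule_class is MoleculeClass.SMALL_MOLECULE:
        return (
            group.molecule_class is MoleculeClass.SMALL_MOLECULE
            and chain.residues[0].name == group.representative_sequence
        )
    if group.molecule_class is MoleculeClass.SMALL_MOLECULE:
        return False
    # Protein vs peptide is a length distinction, not a chemical one.
    if chain.molecule_class.is_amino != group.molecule_class.is_amino:
        return False
    seq = extract_sequence(chain)
    identity = alignment_identity(
        *align_sequences(seq, group.representative_sequence)
    )
    return identity >= identity_threshold


def group_equivalent_chains(
    structure: Structure,
    identity_threshold: float = DEFAULT_CONSTANTS.identity_threshold,
) -> list[ChainGroup]:
    """Partition chains into equivalence groups.

    Polymer chains join a group when their sequence identity to the group
    representative (over aligned columns) reaches *identity_threshold*;
    small molecules group by identical component code.
    """
    groups: list[ChainGroup] = []
    for chain in structure:
        for group in groups:
            if _chains_equivalent(chain, group, identity_threshold):
                group.member_chain_ids.append(chain.chain_id)
                break
        else:
            rep = (
                chain.residues[0].name
                if chain.molecule_class is MoleculeClass.SMALL_MOLECULE
                else extract_sequence(chain)
            )
            groups.append(
                ChainGroup(
                    member_chain_ids=[chain.chain_id],
                    representative_sequence=rep,
                    molecule_class=chain.molecule_class,
                )
            )
    return groups
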
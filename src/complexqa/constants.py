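"""Scoring constants, chemical tables, and CAPRI class boundaries.

All tunables live in one frozen dataclass (:class:`ScoringConstants`) so the
CLI and library share a single source of defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Backbone atom names used for RMSD calculations on amino-acid chains.
PROTEIN_BACKBONE: frozenset[str] = frozenset({"N", "CA", "C", "O"})

#: Backbone atom names for nucleic-acid chains: phosphate plus the primed
#: sugar atoms (unprimed O2/C5 etc. belong to the base and are excluded).
NUCLEIC_BACKBONE: frozenset[str] = frozenset(
    {"P", "OP1", "OP2",
     "O2'", "O3'", "O4'", "O5'",
     "C1'", "C2'", "C3'", "C4'", "C5'"}
)

#: CAPRI quality classes ordered from worst to best.
CAPRI_CLASSES = ("Incorrect", "Acceptable", "Medium", "High")


@dataclass(frozen=True)
class ScoringConstants:
    """Bundle of every numeric constant used by the scorer.

    Attributes
    ----------
    a, b:
        Scale parameters (Å) for the iRMSD and LRMSD terms of the DockQ
        formula.
    contact_cutoff, contact_cutoff_peptide:
        Max heavy-atom distance (Å) for two residues in separate chains to
        count as a contact; the tighter value applies when either chain is
        a peptide.
    interface_cutoff, interface_cutoff_peptide_cb:
        Heavy-atom (resp. Cβ–Cβ for peptides) distance defining interface
        residues for iRMSD.
    clash_cutoff:
        Inter-chain heavy-atom distance below which a pair is a clash.
    peptide_max_len:
        Amino-acid chains of at most this many residues classify as PEPTIDE.
    identity_threshold:
        Sequence identity over aligned columns above which two chains are
        treated as copies of the same subunit.
    covalent_tolerance:
        Slack (Å) added to the covalent radius sum for bond perception.
    match_cap:
        Max number of ligand graph isomorphisms enumerated before bailing.
    """

    a: float = 1.5
    b: float = 8.5
    contact_cutoff: float = 5.0
    contact_cutoff_peptide: float = 4.0
    interface_cutoff: float = 10.0
    interface_cutoff_peptide_cb: float = 8.0
    clash_cutoff: float = 2.0
    peptide_max_len: int = 20
    identity_threshold: float = 0.9
    covalent_tolerance: float = 0.4
    match_cap: int = 10_000
    # DockQ boundaries of the CAPRI classes; half-open on the left:
    # Incorrect < acceptable <= Acceptable < medium <= Medium < high <= High
    capri_acceptable: float = 0.23
    capri_medium: float = 0.49
    capri_high: float = 0.80
    protein_backbone: frozenset = field(default=PROTEIN_BACKBONE)
    nucleic_backbone: frozenset = field(default=NUCLEIC_BACKBONE)


DEFAULT_CONSTANTS = ScoringConstants()

#: Single-bond covalent radii in Å (Cordero et al. 2008 consensus values;
#: low-spin radii for the transition metals that have two).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "D": 0.31, "HE": 0.28,
    "LI": 1.28, "BE": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "NE": 0.58,
    "NA": 1.66, "MG": 1.41, "AL": 1.21, "SI": 1.11, "P": 1.07, "S": 1.05,
    "CL": 1.02, "AR": 1.06,
    "K": 2.03, "CA": 1.76, "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24,
    "CU": 1.32, "ZN": 1.22, "AS": 1.19, "SE": 1.20, "BR": 1.20,
    "MO": 1.54, "RU": 1.46, "AG": 1.45, "CD": 1.44, "I": 1.39, "W": 1.62,
    "PT": 1.36, "AU": 1.36, "HG": 1.32,
}
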
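"""scoring: contacts, fnat, superposition, RMSDs, clashes, DockQ."""

import numpy as np
import pytest

from complexqa.constants import DEFAULT_CONSTANTS, ScoringConstants
from complexqa.errors import InsufficientAtomsError, NoNativeInterfaceError
from complexqa.scoring import (
    classify_capri,
    compute_dockq,
    compute_fnat,
    compute_irmsd,
    compute_lrmsd,
    count_clashes,
    define_interface_residues,
    find_contacts,
    score_interface,
    superpose,
)
from complexqa.structures import Atom, Chain, MoleculeClass, Residue

from conftest import (
    identity_correspondence,
    line_chain,
    protein_residue,
    rotation_about,
    transform_structure,
    two_chain_structure,
)
from oracles import (
    brute_clashes,
    brute_contacts,
    brute_interface_residues,
    quaternion_superpose,
    rmsd_after,
)


def single_residue_chain(chain_id, origin, molecule_class=None):
    chain = Chain(chain_id=chain_id, residues=[protein_residue(1, origin)])
    chain.molecule_class = molecule_class or MoleculeClass.PEPTIDE
    return chain


def one_atom_chain(chain_id, origin):
    res = Residue("ALA", 1, atoms=[Atom("CA", "C", origin)])
    return Chain(chain_id, [res], MoleculeClass.PEPTIDE)


class TestFindContacts:
    def test_pair_inside_cutoff(self):
        # closest (only) heavy atoms at 4.9 Å
        a = one_atom_chain("A", (0, 0, 0))
        b = one_atom_chain("B", (0, 4.9, 0))
        assert find_contacts(a, b, 5.0) == {((1, ""), (1, ""))}

    def test_pair_outside_peptide_cutoff(self):
        a = one_atom_chain("A", (0, 0, 0))
        b = one_atom_chain("B", (0, 4.9, 0))
        assert find_contacts(a, b, 4.0) == frozenset()

    def test_exact_cutoff_included(self):
        a = one_atom_chain("A", (0, 0, 0))
        b = one_atom_chain("B", (0, 5.0, 0))
        assert len(find_contacts(a, b, 5.0)) == 1

    def test_matches_brute_force(self, dimer_chains):
        a, b = dimer_chains
        for cutoff in (4.0, 5.0, 6.5):
            assert find_contacts(a, b, cutoff) == brute_contacts(a, b, cutoff)

    def test_symmetric_up_to_transposition(self, dimer_chains):
        a, b = dimer_chains
        fwd = find_contacts(a, b, 5.0)
        rev = find_contacts(b, a, 5.0)
        assert fwd == {(kb, ka) for ka, kb in rev}


class TestComputeFnat:
    def test_model_equals_native(self, dimer_chains):
        a, b = dimer_chains
        native = find_contacts(a, b, 5.0)
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(b, b)
        fnat, fnonnat, *_ = compute_fnat(native, native, corr_a, corr_b)
        assert fnat == 1.0
        assert fnonnat == 0.0

    def test_three_of_six_plus_one_spurious(self):
        # verified by explicit set arithmetic: 3/6 native kept, 1 of the
        # 4 model contacts is spurious
        a = line_chain("A", n_res=8)
        b = line_chain("B", n_res=8, start=(0, 30, 0))
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(b, b)
        native = frozenset(((i, ""), (i, "")) for i in range(1, 7))
        model = frozenset(
            [((1, ""), (1, "")), ((2, ""), (2, "")), ((3, ""), (3, "")),
             ((7, ""), (8, ""))]
        )
        fnat, fnonnat, n_correct, n_native, n_model = compute_fnat(
            model, native, corr_a, corr_b
        )
        assert fnat == pytest.approx(0.5)
        assert fnonnat == pytest.approx(0.25)
        assert (n_correct, n_native, n_model) == (3, 6, 4)

    def test_empty_model_interface(self, dimer_chains):
        a, b = dimer_chains
        native = find_contacts(a, b, 5.0)
        corr = identity_correspondence(a, a), identity_correspondence(b, b)
        fnat, fnonnat, *_ = compute_fnat(frozenset(), native, *corr)
        assert fnat == 0.0
        assert fnonnat == 0.0

    def test_empty_native_raises(self, dimer_chains):
        a, b = dimer_chains
        corr = identity_correspondence(a, a), identity_correspondence(b, b)
        with pytest.raises(NoNativeInterfaceError):
            compute_fnat(frozenset(), frozenset(), *corr)

    def test_unmapped_model_contacts_count_as_nonnative(self, dimer_chains):
        a, b = dimer_chains
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(b, b)
        native = frozenset([((1, ""), (1, ""))])
        model = frozenset([((1, ""), (1, "")), ((99, ""), (1, ""))])
        fnat, fnonnat, *_ = compute_fnat(model, native, corr_a, corr_b)
        assert fnat == 1.0
        assert fnonnat == pytest.approx(0.5)


class TestSuperpose:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        _, _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot = rotation_about((1, 2, 3), 1.1)
        moved = pts @ rot.T + np.array([4.0, -2.0, 7.0])
        _, _, rmsd = superpose(pts, moved)
        assert rmsd <= 1e-6

    def test_proper_rotation(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(5, 3))
        mov = ref + rng.normal(scale=0.3, size=(5, 3))
        rotation, translation, rmsd = superpose(ref, mov)
        assert np.linalg.det(rotation) == pytest.approx(1.0, abs=1e-9)
        # applying the returned transform reproduces the returned rmsd
        assert rmsd_after(rotation, translation, mov, ref) == pytest.approx(
            rmsd, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(5, 3))
        mov = ref + rng.normal(scale=0.4, size=(5, 3))
        _, _, rmsd = superpose(ref, mov)
        _, _, oracle_rmsd = quaternion_superpose(ref, mov)
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(InsufficientAtomsError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDefineInterfaceResidues:
    def test_included_just_inside(self):
        a = single_residue_chain("A", (0, 0, 0), MoleculeClass.PROTEIN)
        b = single_residue_chain("B", (0, 9.9, 0), MoleculeClass.PROTEIN)
        # closest heavy atoms at 9.9 Å < 10
        set_a, set_b = define_interface_residues(a, b)
        assert set_a == {(1, "")} and set_b == {(1, "")}

    def test_peptide_cb_rule_excludes(self):
        # Cβ–Cβ at 8.2 Å: outside the 8 Å peptide rule even though other
        # heavy atoms are within 10 Å
        a = single_residue_chain("A", (0, 0, 0))
        b = single_residue_chain("B", (0, 8.2, 0))
        assert a.molecule_class is MoleculeClass.PEPTIDE
        cb_a = a.residues[0].atom("CB").coords
        cb_b = b.residues[0].atom("CB").coords
        assert np.linalg.norm(cb_a - cb_b) == pytest.approx(8.2)
        set_a, set_b = define_interface_residues(a, b)
        assert set_a == set() and set_b == set()

    def test_peptide_cb_rule_includes(self):
        a = single_residue_chain("A", (0, 0, 0))
        b = single_residue_chain("B", (0, 7.9, 0))
        set_a, set_b = define_interface_residues(a, b)
        assert set_a == {(1, "")} and set_b == {(1, "")}

    def test_glycine_falls_back_to_ca(self):
        res_a = protein_residue(1, (0, 0, 0), name="GLY", with_cb=False)
        a = Chain("A", [res_a], MoleculeClass.PEPTIDE)
        b = single_residue_chain("B", (0, 7.9, 0))
        set_a, _ = define_interface_residues(a, b)
        assert set_a == {(1, "")}

    def test_matches_brute_force(self, dimer_chains):
        a, b = dimer_chains
        a.molecule_class = MoleculeClass.PROTEIN
        b.molecule_class = MoleculeClass.PROTEIN
        got = define_interface_residues(a, b)
        expected = brute_interface_residues(
            a, b, DEFAULT_CONSTANTS.interface_cutoff
        )
        assert got == expected


class TestComputeIrmsd:
    def _promote(self, *chains):
        for c in chains:
            c.molecule_class = MoleculeClass.PROTEIN

    def test_identity_is_zero(self, dimer_chains):
        a, b = dimer_chains
        self._promote(a, b)
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(b, b)
        assert compute_irmsd(a, b, corr_a, corr_b) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_translated_chain_matches_oracle(self, dimer_chains):
        a, b = dimer_chains
        self._promote(a, b)
        ref = two_chain_structure(a, b)
        model = transform_structure(ref, np.eye(3), (0, 0, 0))
        # translate model chain B by 2 Å along +y (away from A)
        model_b = transform_structure(
            two_chain_structure(model["B"], model["A"]), np.eye(3), (0, 2, 0)
        )["B"]
        corr_a = identity_correspondence(model["A"], a)
        corr_b = identity_correspondence(model_b, b)
        got = compute_irmsd(a, b, corr_a, corr_b)

        # independent oracle: same selection, quaternion superposition
        iface_a, iface_b = brute_interface_residues(
            a, b, DEFAULT_CONSTANTS.interface_cutoff
        )
        ref_coords, mov_coords = [], []
        for ref_chain, model_chain, keys in (
            (a, model["A"], iface_a),
            (b, model_b, iface_b),
        ):
            for key in sorted(keys):
                r_res = ref_chain.residue_by_key(key)
                m_res = model_chain.residue_by_key(key)
                for name in ("C", "CA", "N", "O"):
                    r_atom, m_atom = r_res.atom(name), m_res.atom(name)
                    if r_atom is not None and m_atom is not None:
                        ref_coords.append(r_atom.coords)
                        mov_coords.append(m_atom.coords)
        _, _, expected = quaternion_superpose(
            np.array(ref_coords), np.array(mov_coords)
        )
        assert got == pytest.approx(expected, abs=1e-6)
        assert got > 0.1

    def test_missing_oxygen_uses_intersection(self, dimer_chains):
        a, b = dimer_chains
        self._promote(a, b)
        model_a = line_chain("A", n_res=10, with_o=False)
        model_a.molecule_class = MoleculeClass.PROTEIN
        corr_a = identity_correspondence(model_a, a)
        corr_b = identity_correspondence(b, b)
        with pytest.warns(UserWarning, match="skipped"):
            rmsd = compute_irmsd(a, b, corr_a, corr_b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_atoms(self, dimer_chains):
        a, b = dimer_chains
        # far-apart chains: no interface residues at all
        far = line_chain("B", n_res=10, start=(0, 500, 0))
        far.molecule_class = MoleculeClass.PROTEIN
        self._promote(a)
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(far, far)
        with pytest.raises(InsufficientAtomsError):
            compute_irmsd(a, far, corr_a, corr_b)


class TestComputeLrmsd:
    def test_identity_is_zero(self, dimer_chains):
        a, b = dimer_chains
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(b, b)
        lrmsd, receptor, ligand = compute_lrmsd(a, b, corr_a, corr_b)
        assert lrmsd == pytest.approx(0.0, abs=1e-9)

    def test_receptor_is_larger_chain(self):
        big = line_chain("A", n_res=12)
        small = line_chain("B", n_res=4, start=(0, 4.8, 0))
        corr_a = identity_correspondence(big, big)
        corr_b = identity_correspondence(small, small)
        _, receptor, ligand = compute_lrmsd(big, small, corr_a, corr_b)
        assert (receptor, ligand) == ("A", "B")
        # swapped argument order: still the larger chain
        _, receptor, ligand = compute_lrmsd(small, big, corr_b, corr_a)
        assert (receptor, ligand) == ("A", "B")

    def test_equal_sizes_first_is_receptor(self, dimer_chains):
        a, b = dimer_chains
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(b, b)
        _, receptor, ligand = compute_lrmsd(a, b, corr_a, corr_b)
        assert (receptor, ligand) == ("A", "B")

    def test_rotated_ligand_matches_oracle(self, dimer_chains):
        a, b = dimer_chains
        rot = rotation_about((0, 1, 0), np.pi)
        model_b_struct = transform_structure(
            two_chain_structure(b, a), rot, (0, 0, 0)
        )
        model_b = model_b_struct["B"]
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(model_b, b)
        got, _, _ = compute_lrmsd(a, b, corr_a, corr_b)

        # oracle: receptor superposition is identity (model A == ref A), so
        # LRMSD is the direct backbone RMSD of the rotated ligand chain
        ref_coords, mov_coords = [], []
        for r_res, m_res in zip(b.residues, model_b.residues):
            for name in ("C", "CA", "N", "O"):
                r_atom, m_atom = r_res.atom(name), m_res.atom(name)
                if r_atom is not None and m_atom is not None:
                    ref_coords.append(r_atom.coords)
                    mov_coords.append(m_atom.coords)
        rotation, translation, _ = quaternion_superpose(
            np.array([r.atom(n).coords for r in a.residues for n in ("C", "CA", "N", "O")]),
            np.array([r.atom(n).coords for r in a.residues for n in ("C", "CA", "N", "O")]),
        )
        expected = rmsd_after(rotation, translation, mov_coords, ref_coords)
        assert got == pytest.approx(expected, abs=1e-6)
        assert got > 1.0


class TestCountClashes:
    def test_no_clashes_when_separated(self, dimer_chains):
        a, b = dimer_chains
        assert count_clashes(a, b, 2.0) == 0

    def test_coincident_atoms_clash(self):
        a = single_residue_chain("A", (0, 0, 0))
        b = single_residue_chain("B", (0, 0, 0))
        assert count_clashes(a, b, 2.0) >= 1

    def test_three_constructed_pairs(self):
        # three atom pairs at 1.5 Å, everything else far away
        res_a = Residue(
            "ALA", 1,
            atoms=[
                Atom("N", "N", (0, 0, 0)),
                Atom("CA", "C", (10, 0, 0)),
                Atom("C", "C", (20, 0, 0)),
            ],
        )
        res_b = Residue(
            "ALA", 1,
            atoms=[
                Atom("N", "N", (0, 1.5, 0)),
                Atom("CA", "C", (10, 1.5, 0)),
                Atom("C", "C", (20, 1.5, 0)),
            ],
        )
        a = Chain("A", [res_a], MoleculeClass.PEPTIDE)
        b = Chain("B", [res_b], MoleculeClass.PEPTIDE)
        assert count_clashes(a, b, 2.0) == 3
        assert count_clashes(a, b, 2.0) == brute_clashes(a, b, 2.0)

    def test_strictly_below_cutoff(self):
        a = Chain("A", [Residue("ALA", 1, atoms=[Atom("CA", "C", (0, 0, 0))])],
                  MoleculeClass.PEPTIDE)
        b = Chain("B", [Residue("ALA", 1, atoms=[Atom("CA", "C", (2.0, 0, 0))])],
                  MoleculeClass.PEPTIDE)
        assert count_clashes(a, b, 2.0) == 0

    def test_matches_brute_force(self, dimer_chains):
        a, b = dimer_chains
        for cutoff in (2.0, 3.0, 5.0):
            assert count_clashes(a, b, cutoff) == brute_clashes(a, b, cutoff)


class TestComputeDockq:
    def test_perfect_model(self):
        assert compute_dockq(1.0, 0.0, 0.0) == 1.0

    def test_half_by_construction(self):
        # each of the three terms equals 0.5 at fnat=0.5, iRMSD=a, LRMSD=b
        assert compute_dockq(0.5, 1.5, 8.5) == pytest.approx(0.5)

    def test_incorrect_limit(self):
        # exact formula value is ~2.5e-5 (the LRMSD term decays as (b/x)^2)
        assert compute_dockq(0.0, 1000.0, 1000.0) < 1e-4

    def test_monotone_in_each_argument(self):
        base = compute_dockq(0.5, 2.0, 5.0)
        assert compute_dockq(0.6, 2.0, 5.0) > base
        assert compute_dockq(0.5, 2.5, 5.0) < base
        assert compute_dockq(0.5, 2.0, 6.0) < base

    def test_custom_constants(self):
        constants = ScoringConstants(a=2.0, b=4.0)
        assert compute_dockq(0.5, 2.0, 4.0, constants) == pytest.approx(0.5)


class TestClassifyCapri:
    @pytest.mark.parametrize(
        "dockq,label",
        [
            (0.0, "Incorrect"),
            (0.2299, "Incorrect"),
            (0.23, "Acceptable"),
            (0.4899, "Acceptable"),
            (0.49, "Medium"),
            (0.5, "Medium"),
            (0.7999, "Medium"),
            (0.80, "High"),
            (1.0, "High"),
        ],
    )
    def test_boundaries(self, dockq, label):
        assert classify_capri(dockq) == label


class TestScoreInterface:
    def _score_self(self, a, b):
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(b, b)
        return score_interface(a, b, a, b, corr_a, corr_b)

    def test_self_comparison_identity(self, dimer_chains):
        a, b = dimer_chains
        result = self._score_self(a, b)
        assert result.fnat == 1.0
        assert result.irmsd == pytest.approx(0.0, abs=1e-9)
        assert result.lrmsd == pytest.approx(0.0, abs=1e-9)
        assert result.dockq == pytest.approx(1.0)
        assert result.clashes == 0
        assert result.capri_class == "High"

    def test_dockq_field_consistent_with_formula(self, dimer_chains):
        a, b = dimer_chains
        result = self._score_self(a, b)
        assert result.dockq == pytest.approx(
            compute_dockq(result.fnat, result.irmsd, result.lrmsd)
        )

    def test_growing_perturbation_degrades_score(self, dimer_chains):
        a, b = dimer_chains
        scores = []
        for dy in (0.0, 1.0, 5.0):
            model_b = transform_structure(
                two_chain_structure(b, a), np.eye(3), (0, dy, 0)
            )["B"]
            corr_a = identity_correspondence(a, a)
            corr_b = identity_correspondence(model_b, b)
            scores.append(
                score_interface(a, model_b, a, b, corr_a, corr_b).dockq
            )
        assert scores[0] == pytest.approx(1.0)
        assert scores[0] > scores[1] > scores[2]

    def test_dissociated_model(self, dimer_chains):
        a, b = dimer_chains
        model_b = transform_structure(
            two_chain_structure(b, a), np.eye(3), (0, 100, 0)
        )["B"]
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(model_b, b)
        result = score_interface(a, model_b, a, b, corr_a, corr_b)
        assert result.fnat == 0.0
        assert result.dockq < 0.05
        assert result.capri_class == "Incorrect"

    def test_rigid_invariance(self, dimer_chains):
        a, b = dimer_chains
        ref = two_chain_structure(a, b)
        rot = rotation_about((1, 1, 0), 0.7)
        model = transform_structure(ref, rot, (5, -3, 2))
        corr_a = identity_correspondence(model["A"], a)
        corr_b = identity_correspondence(model["B"], b)
        result = score_interface(model["A"], model["B"], a, b, corr_a, corr_b)
        assert result.fnat == 1.0
        assert result.irmsd == pytest.approx(0.0, abs=1e-6)
        assert result.lrmsd == pytest.approx(0.0, abs=1e-6)
        assert result.dockq == pytest.approx(1.0, abs=1e-6)

    def test_no_native_interface_raises(self, dimer_chains):
        a, _ = dimer_chains
        far = line_chain("B", n_res=10, start=(0, 100, 0))
        corr_a = identity_correspondence(a, a)
        corr_b = identity_correspondence(far, far)
        with pytest.raises(NoNativeInterfaceError):
            score_interface(a, far, a, far, corr_a, corr_b)
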
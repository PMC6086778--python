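"""Verification steps I-IV: hydrogen unification, element/isotope checks,
functional-group normalization, valence verification."""

from collections import Counter

import pytest

from chemstd.mol import Atom, Bond, BondKind, Molecule, Wedge, atom_valence
from chemstd.smiles import read_smiles, write_canonical_smiles
from chemstd.tables import atomic_number
from chemstd.transform import apply_all
from chemstd.verify import (preprocess_hydrogens, verify_element,
                            verify_functional_groups, verify_hydrogen,
                            verify_valence)


def heavy_formula(mol):
    return Counter(a.atomic_number for a in mol.atoms if a.atomic_number != 1)


class TestPreprocess:
    def test_bare_carbon_gets_four_hydrogens(self):
        m = Molecule()
        m.add_atom(Atom(6))
        assert preprocess_hydrogens(m).atoms[0].implicit_h == 4

    def test_charged_nitrogen_default(self):
        m = Molecule()
        m.add_atom(Atom(7, formal_charge=1))
        assert preprocess_hydrogens(m).atoms[0].implicit_h == 4

    def test_explicit_count_wins(self):
        m = read_smiles("[CH3]")
        assert preprocess_hydrogens(m).atoms[0].implicit_h == 3


class TestVerifyElement:
    def test_invalid_isotope_rejected_with_offender(self):
        rej = verify_element(read_smiles("[4Th]"))
        assert rej is not None and rej.atom_indices == [0]

    def test_valid_cases_pass(self):
        assert verify_element(read_smiles("[232Th]")) is None
        assert verify_element(read_smiles("O")) is None
        assert verify_element(read_smiles("[2H]Cl")) is None


class TestVerifyHydrogen:
    def test_explicit_hydrogens_folded(self):
        m = read_smiles("[H]C([H])([H])[H]")
        out = verify_hydrogen(m)
        assert len(out.atoms) == 1 and out.atoms[0].implicit_h == 4

    def test_deuterium_kept_explicit(self):
        m = read_smiles("[2H]C")
        out = verify_hydrogen(m)
        assert sum(1 for a in out.atoms if a.atomic_number == 1) == 1

    def test_charged_hydrogen_kept(self):
        out = verify_hydrogen(read_smiles("[H+].[Cl-]"))
        assert len(out.atoms) == 2

    def test_h2_kept(self):
        out = verify_hydrogen(read_smiles("[H][H]"))
        assert len(out.atoms) == 2

    def test_wedge_hydrogen_kept(self):
        m = read_smiles("[H]C(F)(Cl)Br")
        h = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 1)
        for _, b in m.covalent_neighbors(h):
            b.wedge = Wedge.UP
        m.bonds[0].a1, m.bonds[0].a2 = m.bonds[0].a2, m.bonds[0].a1
        m._rebuild_adj()
        out = verify_hydrogen(m)
        assert any(a.atomic_number == 1 for a in out.atoms)

    def test_pentavalent_nitrogen_with_h_becomes_cation(self):
        # N with 4 explicit bonds and one implicit H -> N+ with none
        m = read_smiles("C[NH](C)(C)C".replace("NH", "N"))
        m.atoms[1].implicit_h = 1       # force valence 5 with one implicit H
        out = verify_hydrogen(m)
        n = out.atoms[1]
        assert (n.formal_charge, n.implicit_h) == (1, 0)

    def test_hypervalent_halogen_with_h_becomes_anion(self):
        m = Molecule()
        cl = m.add_atom(Atom(atomic_number("Cl"), implicit_h=1))
        c = m.add_atom(Atom(6, implicit_h=3))
        m.add_bond(Bond(cl, c, order=2))
        out = verify_hydrogen(m)
        assert (out.atoms[0].formal_charge, out.atoms[0].implicit_h) == (-1, 0)

    def test_nonorganic_atoms_lose_implicit_h(self):
        m = Molecule()
        m.add_atom(Atom(atomic_number("Li"), implicit_h=1))
        out = verify_hydrogen(m)
        assert out.atoms[0].implicit_h == 0


class TestFunctionalGroups:
    def smiles_after(self, smi):
        out, recs = verify_functional_groups(read_smiles(smi))
        return write_canonical_smiles(out), recs

    def test_nitro_charge_separation(self):
        s, recs = self.smiles_after("CN(=O)=O")
        assert s == write_canonical_smiles(read_smiles("C[N+](=O)[O-]"))
        assert [r.transformation_index for r in recs] == [18]

    def test_azide_charge_separation(self):
        s, recs = self.smiles_after("CN=N#N")
        assert s == write_canonical_smiles(read_smiles("CN=[N+]=[N-]"))
        assert 16 in {r.transformation_index for r in recs}

    def test_carbon_monoxide(self):
        s, recs = self.smiles_after("[C]#[O]")
        assert s == write_canonical_smiles(read_smiles("[C-]#[O+]"))
        assert 13 in {r.transformation_index for r in recs}

    def test_already_correct_co_untouched(self):
        s, recs = self.smiles_after("[C-]#[O+]")
        assert not recs

    def test_pyridine_n_oxide_untouched(self):
        s, recs = self.smiles_after("[O-][n+]1ccccc1")
        assert not recs

    def test_ionic_bond_requires_unique_pair(self):
        # two Na+ and one Cl-: ambiguous, no bond set
        out, recs = verify_functional_groups(read_smiles("[Na+].[Na+].[Cl-]"))
        assert not any(b.kind is BondKind.IONIC for b in out.bonds)
        # one Na+ and one Cl-: the unique pair is bonded
        out, recs = verify_functional_groups(read_smiles("[Na+].[Cl-]"))
        assert any(b.kind is BondKind.IONIC for b in out.bonds)
        assert 8 in {r.transformation_index for r in recs}

    def test_covalent_alkali_bond_becomes_ionic_with_charges(self):
        out, recs = verify_functional_groups(read_smiles("CS[Na]"))
        kinds = {b.kind for b in out.bonds}
        assert BondKind.IONIC in kinds
        na = next(i for i, a in enumerate(out.atoms)
                  if a.atomic_number == atomic_number("Na"))
        s = next(i for i, a in enumerate(out.atoms)
                 if a.atomic_number == atomic_number("S"))
        assert out.atoms[na].formal_charge == 1
        assert out.atoms[s].formal_charge == -1

    def test_dative_oxygen_boron(self):
        out, recs = verify_functional_groups(read_smiles("CCO(CC)B(F)(F)F"))
        assert any(b.kind is BondKind.DATIVE for b in out.bonds)
        assert 11 in {r.transformation_index for r in recs}
        # no charges placed
        assert all(a.formal_charge == 0 for a in out.atoms)

    def test_metal_complexation_heme_style(self):
        out, recs = verify_functional_groups(read_smiles("[Fe]N1C=CC=C1"))
        assert any(b.kind is BondKind.COMPLEX for b in out.bonds)
        assert 15 in {r.transformation_index for r in recs}
        n = next(i for i, a in enumerate(out.atoms) if a.atomic_number == 7)
        fe = next(i for i, a in enumerate(out.atoms)
                  if a.atomic_number == atomic_number("Fe"))
        assert out.atoms[n].formal_charge == -1
        assert out.atoms[fe].formal_charge == 1

    def test_metal_oxo_bond_protected(self):
        out, _ = verify_functional_groups(read_smiles("O=[V]"))
        assert all(b.kind is BondKind.COVALENT for b in out.bonds)

    def test_cyclopentadienide(self):
        out, recs = verify_functional_groups(
            read_smiles("[C-]1[C-][C-][C-][C-]1"))
        charges = sorted(a.formal_charge for a in out.atoms)
        assert charges == [-1, 0, 0, 0, 0]
        assert sorted(b.order for b in out.bonds) == [1, 1, 1, 2, 2]
        assert sum(a.implicit_h for a in out.atoms) == 5

    def test_hexaanion_to_benzene(self):
        out, recs = verify_functional_groups(
            read_smiles("[C-]1[C-][C-][C-][C-][C-]1"))
        assert all(a.formal_charge == 0 for a in out.atoms)
        assert sorted(b.order for b in out.bonds) == [1, 1, 1, 2, 2, 2]

    def test_thiophene_standard_form_untouched(self):
        _, recs = verify_functional_groups(read_smiles("C1=CSC=C1"))
        assert not recs

    def test_thiophene_sulfur_double_drawing_fixed(self):
        m = Molecule()
        s = m.add_atom(Atom(atomic_number("S")))
        cs = [m.add_atom(Atom(6)) for _ in range(4)]
        m.add_bond(Bond(s, cs[0], order=2))
        m.add_bond(Bond(cs[0], cs[1], order=1))
        m.add_bond(Bond(cs[1], cs[2], order=2))
        m.add_bond(Bond(cs[2], cs[3], order=1))
        m.add_bond(Bond(cs[3], s, order=1))
        for i, c in enumerate(cs):
            m.atoms[c].implicit_h = [1, 1, 1, 2][i]
        out, recs = verify_functional_groups(m)
        assert 34 in {r.transformation_index for r in recs}
        ring_orders = sorted(b.order for b in out.bonds)
        assert ring_orders == [1, 1, 1, 2, 2]
        s_bonds = [b.order for _, b in out.covalent_neighbors(0)]
        assert s_bonds == [1, 1]

    def test_idempotence(self, corpus):
        cases = ["CN(=O)=O", "CN=N#N", "[C]#[O]", "CS[Na]", "[Fe]N1C=CC=C1",
                 "[C-]1[C-][C-][C-][C-]1", "CCO(CC)B(F)(F)F"]
        mols = [read_smiles(s) for s in cases] + list(corpus[:10])
        for m in mols:
            once, _ = verify_functional_groups(m)
            twice, recs2 = verify_functional_groups(once)
            assert not recs2
            assert write_canonical_smiles(twice) == write_canonical_smiles(once)

    def test_heavy_atom_multiset_preserved(self, corpus):
        for m in list(corpus[:15]) + [read_smiles("CN(=O)=O")]:
            out, _ = verify_functional_groups(m)
            assert heavy_formula(out) == heavy_formula(m)


class TestVerifyValence:
    def test_tetravalent_oxygen_rejected(self):
        rej = verify_valence(read_smiles("C=O=C"))
        assert rej is not None
        o = next(i for i, a in enumerate(read_smiles("C=O=C").atoms)
                 if a.atomic_number == 8)
        assert o in rej.atom_indices

    def test_pentavalent_carbon_rejected(self):
        assert verify_valence(read_smiles("CC(C)(C)(C)C")) is not None

    def test_benzene_passes(self):
        assert verify_valence(read_smiles("c1ccccc1")) is None

    def test_offending_atoms_all_listed(self):
        rej = verify_valence(read_smiles("O(=C)=C.O(=C)=C"))
        assert rej is not None and len(rej.atom_indices) == 2
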
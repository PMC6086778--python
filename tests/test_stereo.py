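"""Stereochemistry standardization: eligibility, parity reconciliation,
E/Z perception, stripping of invalid annotation."""

import math
import random

import pytest

from chemstd.mol import (Atom, Bond, BondKind, Molecule, Wedge,
                         symmetry_classes)
from chemstd.smiles import read_smiles, write_canonical_smiles
from chemstd.stereo import (double_bond_eligibility, resolve_double_bond,
                            resolve_tetrahedral, standardize_stereo,
                            tetrahedral_eligibility)
from chemstd.tables import atomic_number


def _classes_and_arom(mol):
    classes = symmetry_classes(mol)
    arom = set()
    for b in mol.bonds:
        if b.aromatic:
            arom |= {b.a1, b.a2}
    return classes, arom


def eligibility(mol, i):
    classes, arom = _classes_and_arom(mol)
    return tetrahedral_eligibility(mol, i, classes, arom)


class TestTetrahedralEligibility:
    def test_genuine_center(self):
        m = read_smiles("FC(Cl)Br")
        c = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 6)
        ok, _ = eligibility(m, c)
        assert ok

    def test_glycerol_centre_rejected_by_symmetry(self):
        m = read_smiles("OCC(O)CO")
        c = next(i for i in range(len(m.atoms))
                 if m.atoms[i].atomic_number == 6 and m.degree(i) == 3)
        ok, reason = eligibility(m, c)
        assert not ok and "symmetry" in reason

    def test_two_hydrogens_rejected(self):
        m = read_smiles("FCCl")
        c = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 6)
        ok, reason = eligibility(m, c)
        assert not ok and "hydrogen" in reason

    def test_nitrogen_with_hydrogen_rejected(self):
        m = read_smiles("CN(O)F".replace("O", "OC"))  # CN(OC)F: N has no H
        n = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 7)
        ok, _ = eligibility(m, n)
        assert not ok       # tri-coordinated N is not tetra-valent anyway
        m2 = read_smiles("CN(C)C")
        n2 = next(i for i, a in enumerate(m2.atoms) if a.atomic_number == 7)
        assert not eligibility(m2, n2)[0]

    def test_phosphorus_two_like_mesomeric_ligands_achiral(self):
        m = read_smiles("OP(=O)(OC)C")     # O=P-OH: achiral
        p = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 15)
        ok, reason = eligibility(m, p)
        assert not ok and "mesomeric" in reason

    def test_phosphorus_mixed_mesomeric_ligands_chiral(self):
        m = read_smiles("OP(=S)(OC)C")     # S=P-OH: can be chiral
        p = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 15)
        ok, _ = eligibility(m, p)
        assert ok

    def test_trivalent_phosphine_eligible(self):
        m = read_smiles("CP(N)OC")
        p = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 15)
        assert eligibility(m, p)[0]

    def test_hexavalent_sulfur_next_to_ch_rejected(self):
        m = read_smiles("CS(=O)(=N)F".replace("=N", "=NC"))
        s = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 16)
        ok, reason = eligibility(m, s)
        assert not ok


class TestTetrahedralResolution:
    def _wedge_molecule(self, wedge_up=True, annotate=None):
        """2-D CHFClBr with one wedge at the centre."""
        m = Molecule()
        c = m.add_atom(Atom(6, implicit_h=1,
                            coords=(0.0, 0.0, 0.0)))
        f = m.add_atom(Atom(9, coords=(1.0, 0.0, 0.0)))
        cl = m.add_atom(Atom(17, coords=(-0.5, 0.87, 0.0)))
        br = m.add_atom(Atom(35, coords=(-0.5, -0.87, 0.0)))
        b = Bond(c, f, order=1)
        b.wedge = Wedge.UP if wedge_up else Wedge.DOWN
        m.add_bond(b)
        m.add_bond(Bond(c, cl, order=1))
        m.add_bond(Bond(c, br, order=1))
        m.dimensionality = 2
        if annotate is not None:
            m.atoms[c].tet_stereo = annotate
        return m, c

    def test_wedge_defines_parity(self):
        m, c = self._wedge_molecule(True)
        assert resolve_tetrahedral(m, c) is not None

    def test_mirror_wedge_flips_parity(self):
        m1, c = self._wedge_molecule(True)
        m2, _ = self._wedge_molecule(False)
        r1 = resolve_tetrahedral(m1, c)
        r2 = resolve_tetrahedral(m2, c)
        assert r1[0] == r2[0] and r1[1] != r2[1]

    def test_no_wedges_in_2d_is_undefined(self):
        m, c = self._wedge_molecule(True)
        m.bonds[0].wedge = Wedge.NONE
        assert resolve_tetrahedral(m, c) is None

    def test_annotation_contradicting_wedge_is_undefined(self):
        m, c = self._wedge_molecule(True)
        derived = resolve_tetrahedral(m, c)
        contradiction = (derived[0], 3 - derived[1])
        m.atoms[c].tet_stereo = contradiction
        assert resolve_tetrahedral(m, c) is None

    def test_agreeing_annotation_kept(self):
        m, c = self._wedge_molecule(True)
        derived = resolve_tetrahedral(m, c)
        m.atoms[c].tet_stereo = derived
        assert resolve_tetrahedral(m, c) == derived

    def test_3d_mirror_flips_parity(self):
        def build(sign):
            m = Molecule()
            c = m.add_atom(Atom(6, coords=(0, 0, 0)))
            zs = [9, 17, 35, 7]
            pos = [(1, 1, sign * 1), (1, -1, -sign * 1),
                   (-1, 1, -sign * 1), (-1, -1, sign * 1)]
            for z, p in zip(zs, pos):
                j = m.add_atom(Atom(z, coords=p))
                m.add_bond(Bond(c, j, order=1))
            m.dimensionality = 3
            return m, c
        m1, c = build(+1)
        m2, _ = build(-1)
        r1, r2 = resolve_tetrahedral(m1, c), resolve_tetrahedral(m2, c)
        assert r1[1] != r2[1]


def _planar_butene(angle_deg=120.0, same_side=False, dim=2):
    """2-butene drawn in the plane; substituent geometry controllable."""
    m = Molecule()
    c1 = m.add_atom(Atom(6, implicit_h=1, coords=(0.0, 0.0, 0.0)))
    c2 = m.add_atom(Atom(6, implicit_h=1, coords=(1.0, 0.0, 0.0)))
    th = math.radians(angle_deg)
    me1 = m.add_atom(Atom(6, implicit_h=3,
                          coords=(-math.cos(math.pi - th),
                                  math.sin(math.pi - th), 0.0)))
    y2 = math.sin(math.pi - th) * (1 if same_side else -1)
    me2 = m.add_atom(Atom(6, implicit_h=3,
                          coords=(1.0 + math.cos(math.pi - th), y2, 0.0)))
    db = Bond(c1, c2, order=2)
    m.add_bond(db)
    m.add_bond(Bond(c1, me1, order=1))
    m.add_bond(Bond(c2, me2, order=1))
    m.dimensionality = dim
    return m, db


class TestDoubleBonds:
    def test_cyclohexene_ring_too_small(self):
        m = read_smiles("C1CCC=CC1")
        b = next(b for b in m.bonds if b.order == 2)
        classes, arom = _classes_and_arom(m)
        assert double_bond_eligibility(m, b, classes, arom) == "ineligible"

    def test_butene_eligible(self):
        m, db = _planar_butene()
        classes, arom = _classes_and_arom(m)
        assert double_bond_eligibility(m, db, classes, arom) == "eligible"

    def test_terminal_methylene_undefined(self):
        m = read_smiles("C=CC")
        b = next(b for b in m.bonds if b.order == 2)
        classes, arom = _classes_and_arom(m)
        assert double_bond_eligibility(m, b, classes, arom) != "eligible"

    def test_trans_coordinates_give_trans(self):
        m, db = _planar_butene(same_side=False)
        classes, _ = _classes_and_arom(m)
        out = resolve_double_bond(m, db, classes)
        assert isinstance(out, tuple) and out[2] == "trans"

    def test_cis_coordinates_give_cis(self):
        m, db = _planar_butene(same_side=True)
        classes, _ = _classes_and_arom(m)
        out = resolve_double_bond(m, db, classes)
        assert isinstance(out, tuple) and out[2] == "cis"

    def test_near_collinear_substituent_undefined(self):
        m, db = _planar_butene(angle_deg=175.0)
        classes, _ = _classes_and_arom(m)
        assert resolve_double_bond(m, db, classes) == "undefined"

    def test_deposited_crossed_bond_stays_undefined(self):
        m, db = _planar_butene(same_side=False)
        db.crossed = True
        db.db_stereo = "undefined"
        classes, _ = _classes_and_arom(m)
        assert resolve_double_bond(m, db, classes) == "undefined"


class TestStandardizeStereo:
    def test_glycerol_annotation_removed(self, standardizer):
        res = standardizer.standardize("OC[C@H](O)CO")
        assert "@" not in res.key

    def test_achiral_phosphorus_annotation_removed(self, standardizer):
        res = standardizer.standardize("O[P@](=O)(O)C")
        assert "@" not in res.key

    def test_genuine_center_retained(self, standardizer):
        res = standardizer.standardize("F[C@H](Cl)Br")
        assert "@" in res.key

    def test_swapping_substituents_flips_output(self, standardizer):
        k1 = standardizer.standardize("F[C@H](Cl)Br").key
        k2 = standardizer.standardize("F[C@@H](Cl)Br").key
        assert k1 != k2

    def test_no_stereo_molecule_unchanged(self):
        m = read_smiles("CCO")
        out, rec = standardize_stereo(m)
        assert (rec.added, rec.modified, rec.removed) == (0, 0, 0)
        assert write_canonical_smiles(out) == write_canonical_smiles(m)

    def test_stripping_complete(self, standardizer, corpus):
        for mol in corpus[:10]:
            res = standardizer.standardize(mol)
            if not res.accepted:
                continue
            out = res.molecule
            classes = symmetry_classes(out)
            arom = set()
            for b in out.bonds:
                if b.aromatic:
                    arom |= {b.a1, b.a2}
            for i, a in enumerate(out.atoms):
                if a.tet_stereo is not None:
                    assert tetrahedral_eligibility(out, i, classes, arom)[0]

    def test_counts_recorded(self, standardizer):
        res = standardizer.standardize("OC[C@H](O)CO")
        assert res.stereo_changes.removed >= 1

    def test_label_invariance_of_retained_stereo(self, standardizer):
        m = read_smiles("C[C@@H](N)C(=O)O")
        ref = standardizer.standardize(m).key
        rng = random.Random(21)
        for _ in range(10):
            perm = list(range(len(m.atoms)))
            rng.shuffle(perm)
            assert standardizer.standardize(m.permuted(perm)).key == ref
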
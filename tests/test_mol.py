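"""Molecular graph model: valence accounting, components, symmetry classes
and canonical ordering."""

import random

import networkx as nx
import pytest

from chemstd.mol import (Atom, Bond, BondKind, Molecule, atom_valence,
                         canonical_order, covalent_components,
                         smallest_ring_size, symmetry_classes)
from chemstd.smiles import read_smiles
from chemstd.tables import atomic_number


def test_methane_valence():
    m = read_smiles("C")
    assert atom_valence(m, 0) == 4


def test_zero_order_bonds_do_not_contribute_to_valence():
    # heme-style nitrogen: two ring bonds (orders 1 and 2) plus a complex
    # bond to iron
    m = Molecule()
    n = m.add_atom(Atom(atomic_number("N")))
    c1 = m.add_atom(Atom(6))
    c2 = m.add_atom(Atom(6))
    fe = m.add_atom(Atom(atomic_number("Fe"), formal_charge=2))
    m.add_bond(Bond(n, c1, order=1))
    m.add_bond(Bond(n, c2, order=2))
    m.add_bond(Bond(n, fe, order=1, kind=BondKind.COMPLEX))
    assert atom_valence(m, n) == 3
    # removing the complex bond changes nothing
    m2 = m.copy()
    m2.remove_bond_between(n, fe)
    assert atom_valence(m2, n) == 3


def test_carbon_monoxide_oxygen_valence():
    m = read_smiles("[C-]#[O+]")
    o = next(i for i, a in enumerate(m.atoms) if a.atomic_number == 8)
    assert atom_valence(m, o) == 3


def test_ionic_pair_is_two_components():
    m = Molecule()
    na = m.add_atom(Atom(atomic_number("Na"), formal_charge=1))
    cl = m.add_atom(Atom(atomic_number("Cl"), formal_charge=-1))
    m.add_bond(Bond(na, cl, order=1, kind=BondKind.IONIC))
    assert len(covalent_components(m)) == 2


def test_benzene_is_one_component():
    assert len(covalent_components(read_smiles("c1ccccc1"))) == 1


def test_complex_centre_and_ligands_separate():
    # Zr-style centre complex-bonded to two ligands plus a free Cl-
    m = Molecule()
    zr = m.add_atom(Atom(atomic_number("Zr"), formal_charge=2))
    cl = m.add_atom(Atom(atomic_number("Cl"), formal_charge=-1))
    lig = [m.add_atom(Atom(6)) for _ in range(4)]
    m.add_bond(Bond(lig[0], lig[1], order=2))
    m.add_bond(Bond(lig[2], lig[3], order=2))
    m.add_bond(Bond(zr, lig[0], order=1, kind=BondKind.COMPLEX))
    m.add_bond(Bond(zr, lig[2], order=1, kind=BondKind.COMPLEX))
    comps = covalent_components(m)
    assert len(comps) == 4      # Zr, Cl and the two two-atom ligands


class TestSymmetryClasses:
    def test_benzene_single_class(self):
        m = read_smiles("c1ccccc1")
        assert len(set(symmetry_classes(m))) == 1

    def test_glycerol_centre_has_equivalent_arms(self):
        m = read_smiles("OCC(O)CO")
        classes = symmetry_classes(m)
        centre = next(i for i in range(len(m.atoms))
                      if m.atoms[i].atomic_number == 6 and m.degree(i) == 3)
        nbr = [classes[j] for j, _ in m.covalent_neighbors(centre)]
        assert len(set(nbr)) < len(nbr)     # the two CH2OH arms coincide

    def test_halomethane_all_neighbors_distinct(self):
        m = read_smiles("FC(Cl)Br")
        classes = symmetry_classes(m)
        c = next(i for i in range(len(m.atoms))
                 if m.atoms[i].atomic_number == 6)
        nbr = [classes[j] for j, _ in m.covalent_neighbors(c)]
        assert len(set(nbr)) == len(nbr)

    def test_explicit_hydrogen_pinned_to_class_zero(self):
        m = read_smiles("[H]C([H])([H])F")
        classes = symmetry_classes(m)
        for i, a in enumerate(m.atoms):
            if a.atomic_number == 1:
                assert classes[i] == 0
            else:
                assert classes[i] > 0

    def test_agrees_with_automorphism_orbits_on_small_graphs(self, corpus):
        """Same class must imply a graph automorphism mapping the atoms."""
        for mol in corpus:
            if len(mol.atoms) > 8:
                continue
            classes = symmetry_classes(mol)
            orbits = _automorphism_orbits(mol)
            for i in range(len(mol.atoms)):
                for j in range(i + 1, len(mol.atoms)):
                    if classes[i] == classes[j]:
                        assert orbits[i] == orbits[j], \
                            f"atoms {i},{j} share a class but not an orbit"


def _automorphism_orbits(mol):
    g = nx.Graph()
    for i, a in enumerate(mol.atoms):
        g.add_node(i, kind=(a.atomic_number, a.formal_charge, a.implicit_h,
                            a.isotope_mass))
    for b in mol.bonds:
        g.add_edge(b.a1, b.a2, order=(b.order, b.kind.value))
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda x, y: x["kind"] == y["kind"],
        edge_match=lambda x, y: x["order"] == y["order"])
    orbit = {i: {i} for i in g.nodes}
    for mapping in gm.isomorphisms_iter():
        for a, b in mapping.items():
            orbit[a].add(b)
    return {i: frozenset(s) for i, s in orbit.items()}


class TestCanonicalOrder:
    def test_single_atom_identity(self):
        m = read_smiles("[Na+]")
        assert canonical_order(m) == [0]

    def test_toluene_methyl_distinct(self):
        m = read_smiles("Cc1ccccc1")
        rank = canonical_order(m)
        assert len(set(rank)) == len(rank)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_label_invariance(self, corpus, seed):
        """The canonical *form* is invariant under relabeling (automorphic
        atoms may swap ranks, so individual ranks are compared via the
        canonicalized structure, not atom by atom)."""
        rng = random.Random(seed)
        for mol in corpus[:15]:
            n = len(mol.atoms)
            perm = list(range(n))
            rng.shuffle(perm)
            moved = mol.permuted(perm)
            assert _canonical_form(mol) == _canonical_form(moved)


def _canonical_form(mol):
    rank = canonical_order(mol)
    m = mol.permuted(rank)
    atoms = tuple((a.atomic_number, a.formal_charge, a.implicit_h,
                   a.isotope_mass) for a in m.atoms)
    edges = tuple(sorted((min(b.a1, b.a2), max(b.a1, b.a2), b.order,
                          b.kind.value) for b in m.bonds))
    return atoms, edges


def test_smallest_ring_size():
    m = read_smiles("C1CC1CCC")
    ring_atom = 0
    assert smallest_ring_size(m, ring_atom) == 3
    chain_atom = len(m.atoms) - 1
    assert smallest_ring_size(m, chain_atom) == 0


def test_duplicate_and_self_bonds_rejected():
    m = Molecule()
    a = m.add_atom(Atom(6))
    b = m.add_atom(Atom(6))
    m.add_bond(Bond(a, b))
    with pytest.raises(ValueError):
        m.add_bond(Bond(a, b, order=2))
    with pytest.raises(ValueError):
        m.add_bond(Bond(a, a))
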
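"""Programmatic fixtures: the worked examples every rule family must
handle, plus a seeded random corpus of small organic molecules.

Nothing is downloaded: every case is regenerated from an inline SMILES or
molfile text.  Cases whose full connection table is not published are
simplified stand-ins exercising the same code path and are labeled as
such in their provenance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .mol import Atom, Bond, Molecule
from .smiles import read_smiles
from .tables import atomic_number

__all__ = ["FixtureCase", "paper_fixtures", "random_corpus",
           "pathological_conjugated"]


@dataclass
class FixtureCase:
    name: str
    smiles: str | None = None
    molblock: str | None = None
    expected: str = "accept"            # "accept" or "reject"
    reject_step: str | None = None
    group: str | None = None            # cases in a group share a CompoundKey
    transform_index: int | None = None  # a transformation expected to fire
    provenance: str = ""

    def molecule(self) -> Molecule:
        if self.smiles is not None:
            return read_smiles(self.smiles)
        from .sdf import parse_molblock
        mol, _ = parse_molblock(self.molblock.splitlines())
        return mol


# Guanine drawn eight ways: lactam/lactim x N7H/N9H tautomers, aromatic and
# Kekulé input, one form with explicit ring hydrogens.  All are C5H5N5O.
_GUANINE_VARIANTS = [
    "Nc1nc2[nH]cnc2c(=O)[nH]1",          # 9H lactam, aromatic input
    "NC1=NC2=C(N=CN2)C(=O)N1",           # 9H lactam, Kekulé input
    "O=C1NC(N)=NC2=C1N=CN2",             # same Kekulé form, different root
    "Nc1nc2[nH]cnc2c(O)n1",              # lactim, aromatic input
    "NC1=NC2=C(N=CN2)C(O)=N1",           # lactim, Kekulé input
    "NC1=NC2=C(C(O)=N1)N=CN2",           # lactim written from the other ring
    "NC1=NC2=C(N=CN2[H])C(=O)N1[H]",     # explicit hydrogens on ring N
    "O=c1[nH]c(N)nc2[nH]cnc12",          # aromatic input, different root
]


def paper_fixtures() -> list[FixtureCase]:
    cases: list[FixtureCase] = []
    for k, smi in enumerate(_GUANINE_VARIANTS, 1):
        cases.append(FixtureCase(
            name=f"guanine_variant_{k}", smiles=smi, group="guanine",
            provenance="guanine deposited in eight non-identical forms"))
    cases += [
        FixtureCase("pyrimidinone_lactam", smiles="O=C1C=CNC=N1",
                    group="pyrimidinone",
                    provenance="pyrimidin-4-one tautomer set"),
        FixtureCase("pyrimidinone_lactim", smiles="Oc1ccncn1",
                    group="pyrimidinone",
                    provenance="pyrimidin-4-one tautomer set"),
        FixtureCase("thioacetic_thiol", smiles="CC(S)=O", group="thioacetic",
                    provenance="thioacetic acid tautomers"),
        FixtureCase("thioacetic_thione", smiles="CC(=S)O", group="thioacetic",
                    provenance="thioacetic acid tautomers"),
        # verification failures
        FixtureCase("tetravalent_oxygen", smiles="C=O=C", expected="reject",
                    reject_step="verify_valence",
                    provenance="tetra-valent oxygen rejection"),
        FixtureCase("pentavalent_carbon", smiles="CC(C)(C)(C)C",
                    expected="reject", reject_step="verify_valence",
                    provenance="penta-valent carbon rejection"),
        FixtureCase("adjacent_n_plus", smiles="C[N+](C)(C)[N+](C)(C)C",
                    expected="reject", reject_step="standardize_valence_bond",
                    provenance="neighboring like charges rejection"),
        FixtureCase("invalid_isotope_thorium", smiles="[4Th]",
                    expected="reject", reject_step="verify_element",
                    provenance="4-Da thorium isotope"),
        FixtureCase("valid_isotope_thorium", smiles="[232Th]",
                    provenance="232Th, 100% natural abundance"),
        # functional-group transformations
        FixtureCase("azide_neutral", smiles="CN=N#N", transform_index=16,
                    provenance="azide charge separation"),
        FixtureCase("nitro_pentavalent", smiles="CN(=O)=O", transform_index=18,
                    provenance="nitro penta-valent drawing"),
        FixtureCase("nitrate_pentavalent", smiles="ON(=O)=O",
                    transform_index=18, provenance="nitrate drawing"),
        FixtureCase("carbon_monoxide", smiles="[C]#[O]", transform_index=13,
                    provenance="neutral C#O to [C-]#[O+]"),
        FixtureCase("sodium_thiolate_covalent", smiles="CS[Na]",
                    transform_index=9,
                    provenance="ionic bond perception, thiopental-style"),
        FixtureCase("boron_etherate", smiles="CCO(CC)B(F)(F)F",
                    transform_index=11,
                    provenance="dative O->B bond, BF3 etherate style"),
        FixtureCase("iron_pyrrole_complex", smiles="[Fe]N1C=CC=C1",
                    transform_index=15,
                    provenance="complex bond to Fe, heme-style stand-in"),
        FixtureCase("cyclopentadienyl_pentaanion",
                    smiles="[C-]1[C-][C-][C-][C-]1", transform_index=32,
                    provenance="metallocene ring drawing"),
        FixtureCase("benzene_hexaanion",
                    smiles="[C-]1[C-][C-][C-][C-][C-]1", transform_index=33,
                    provenance="hexa-anionic cyclohexane"),
        FixtureCase("thiophene", smiles="c1ccsc1",
                    provenance="thiophene standard form (no-op)"),
        # tautomer preference pairs
        FixtureCase("amide", smiles="CC(N)=O", group="acetamide",
                    provenance="amide preferred over imidic acid"),
        FixtureCase("imidic_acid", smiles="CC(=N)O", group="acetamide",
                    provenance="amide preferred over imidic acid"),
        FixtureCase("thioamide", smiles="CC(N)=S", group="thioacetamide",
                    provenance="thioamide directionality"),
        FixtureCase("thioimidic_acid", smiles="CC(=N)S", group="thioacetamide",
                    provenance="thioamide directionality"),
        # acyclic N-methylacetamidine forms tie under the printed criteria
        # (equal H-on-N); a cyclic amidine resolves via fewer H on ring atoms
        FixtureCase("amidine_amino", smiles="NC1=NCCCN1", group="amidine",
                    provenance="cyclic amidine directionality"),
        FixtureCase("amidine_imino", smiles="N=C1NCCCN1", group="amidine",
                    provenance="cyclic amidine directionality"),
        # stereochemistry
        FixtureCase("glycerol_false_center", smiles="OC[C@H](O)CO",
                    group="glycerol",
                    provenance="glycerol central carbon is not a stereocenter"),
        FixtureCase("glycerol_plain", smiles="OCC(O)CO", group="glycerol",
                    provenance="glycerol reference"),
        FixtureCase("phosphonic_achiral", smiles="O[P@](=O)(O)C",
                    group="mpa", provenance="O=P-OH achiral phosphorus"),
        FixtureCase("phosphonic_plain", smiles="OP(=O)(O)C", group="mpa",
                    provenance="O=P-OH achiral phosphorus"),
        FixtureCase("chiral_center", smiles="F[C@H](Cl)Br",
                    provenance="bromochlorofluoromethane, genuine center"),
        FixtureCase("cyclohexene", smiles="C1CCC=CC1",
                    provenance="small-ring double bond not stereogenic"),
        FixtureCase("trans_butene", smiles="C/C=C/C",
                    provenance="acyclic stereogenic double bond"),
        # nonstandard bond round trip exemplar
        FixtureCase("magnesium_salt", smiles="[Mg+2].[O-]C(=O)C",
                    provenance="ionic pairing stand-in"),
    ]
    return cases


def pathological_conjugated(n_arms: int = 8,
                            arm: str = "C=CC=CC=CC=C[CH2-]") -> str:
    """SMILES of a tautomer-enumeration stress case.

    Independent conjugated carbanion arms on a saturated backbone: the
    mobile negative charges make the reachable valence-bond forms the
    product of the per-arm state counts, the structure class that dominates
    enumeration blow-ups in practice.  Eight default arms exceed the
    250,000-state cap.
    """
    arms = [f"({arm})" for _ in range(n_arms)]
    parts = []
    for k in range(0, n_arms, 2):
        parts.append("C" + "".join(arms[k:k + 2]))
    return "".join(parts)


# --------------------------------------------------------------------------
# Random corpus
# --------------------------------------------------------------------------

_CORPUS_ELEMENTS = [
    (atomic_number("C"), 4, 0.55),
    (atomic_number("N"), 3, 0.18),
    (atomic_number("O"), 2, 0.18),
    (atomic_number("S"), 2, 0.09),
]


def random_corpus(seed: int, n: int, max_heavy: int = 12) -> list[Molecule]:
    """Seeded random small organic molecules.

    Grows random trees over C/N/O/S with occasional double/triple bonds
    and ring closures, then fills hydrogens by the default valence model.
    Heteroatom and carbonyl density is chosen so that proton-mobile
    groups (amide, enol, imine patterns) are common, mimicking the high
    prevalence of tautomerism in deposited structures.
    """
    if n <= 0 or max_heavy < 1:
        raise ValueError("n and max_heavy must be positive")
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        out.append(_random_molecule(rng, max_heavy))
    return out


def _pick_element(rng):
    r = rng.random()
    acc = 0.0
    for z, val, w in _CORPUS_ELEMENTS:
        acc += w
        if r <= acc:
            return z, val
    return _CORPUS_ELEMENTS[0][:2]


def _random_molecule(rng: random.Random, max_heavy: int) -> Molecule:
    n_heavy = rng.randint(3, max_heavy)
    mol = Molecule()
    z, val = _pick_element(rng)
    mol.add_atom(Atom(z))
    free = {0: val}
    while len(mol.atoms) < n_heavy:
        anchors = [i for i, f in free.items() if f >= 1]
        if not anchors:
            break
        i = rng.choice(anchors)
        z, val = _pick_element(rng)
        order = 1
        has_double = any(b.order >= 2 for _, b in mol.covalent_neighbors(i))
        if free[i] >= 2 and val >= 2 and not has_double and rng.random() < 0.40:
            order = 2
            if free[i] >= 3 and val >= 3 and rng.random() < 0.07:
                order = 3
        j = mol.add_atom(Atom(z))
        mol.add_bond(Bond(i, j, order=order))
        free[i] -= order
        free[j] = val - order
        # seed proton-mobile motifs: a double bond to a heteroatom acceptor
        # frequently gets an N/O donor on the same center (amide, amidine,
        # oxime-type H-X-Y=Z patterns)
        if order == 2 and z in (7, 8, 16) and free[i] >= 1 \
                and len(mol.atoms) < n_heavy and rng.random() < 0.7:
            zd = 7 if rng.random() < 0.6 else 8
            k = mol.add_atom(Atom(zd))
            mol.add_bond(Bond(i, k, order=1))
            free[i] -= 1
            free[k] = (3 if zd == 7 else 2) - 1
    # attach a complete donor/acceptor motif (amide, amidine, thioamide,
    # carboxyl) so proton-mobile groups are common in the corpus
    if n_heavy >= 6 and rng.random() < 0.65:
        anchors = [i for i, f in free.items() if f >= 1]
        if anchors:
            i = rng.choice(anchors)
            z_acc = rng.choice([7, 8, 8, 16])
            z_don = rng.choice([7, 7, 8])
            c = mol.add_atom(Atom(6))
            mol.add_bond(Bond(i, c, order=1))
            free[i] -= 1
            x = mol.add_atom(Atom(z_acc))
            mol.add_bond(Bond(c, x, order=2))
            free[x] = (3 if z_acc == 7 else 2) - 2
            y = mol.add_atom(Atom(z_don))
            mol.add_bond(Bond(c, y, order=1))
            free[y] = (3 if z_don == 7 else 2) - 1
            free[c] = 0
    # occasional ring closure
    if rng.random() < 0.30:
        open_atoms = [i for i, f in free.items() if f >= 1]
        rng.shuffle(open_atoms)
        for a in open_atoms:
            for b in open_atoms:
                if b <= a or mol.bond_between(a, b) is not None:
                    continue
                # only close reasonable ring sizes
                from .mol import smallest_ring_size
                mol.add_bond(Bond(a, b, order=1))
                sz = smallest_ring_size(mol, a, b)
                if 5 <= sz <= 7:
                    free[a] -= 1
                    free[b] -= 1
                else:
                    mol.remove_bond_between(a, b)
                    continue
                break
            else:
                continue
            break
    from .tables import default_implicit_hydrogens
    for i, a in enumerate(mol.atoms):
        s = sum(b.order for _, b in mol.covalent_neighbors(i))
        a.implicit_h = default_implicit_hydrogens(a.atomic_number, 0, s)
    return mol
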
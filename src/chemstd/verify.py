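"""Structure verification: element/isotope validity, hydrogen unification,
functional-group normalization and valence verification (pipeline steps
I-IV), plus the hydrogen pre-processing applied before step I.

These steps either repair atom-local problems (hydrogen counts,
charge/valence mismatches, known nonstandard functional-group drawings) or
reject the record; the heavy-atom element multiset is never changed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import tables
from .mol import BondKind, Molecule, Wedge, atom_valence, sigma_pi_counts
from .tables import ElementClass, classify_element

log = logging.getLogger(__name__)

__all__ = [
    "RejectionReason", "TransformationRecord",
    "preprocess_hydrogens", "verify_element", "verify_hydrogen",
    "verify_functional_groups", "verify_valence",
]

STEP_NAMES = [
    "verify_element", "verify_hydrogen", "verify_functional_groups",
    "verify_valence", "standardize_annotations", "standardize_valence_bond",
    "standardize_aromaticity", "standardize_stereochemistry",
    "standardize_explicit_hydrogens",
]


@dataclass
class RejectionReason:
    step: str
    message: str
    atom_indices: list[int] = field(default_factory=list)

    def __str__(self) -> str:
        return f"[{self.step}] {self.message} (atoms {self.atom_indices})"


@dataclass
class TransformationRecord:
    transformation_index: int
    atom_indices: list[int]
    description: str


def preprocess_hydrogens(mol: Molecule) -> Molecule:
    """Unify hydrogen representation: fill implicit counts by the default
    valence model wherever the record did not pin an explicit count.

    Assumes bond orders and formal charges are correct.
    """
    out = mol.copy()
    for i, a in enumerate(out.atoms):
        if a.explicit_h_spec or a.atomic_number == 1:
            continue
        s = sum(b.order for _, b in out.covalent_neighbors(i))
        h = tables.default_implicit_hydrogens(a.atomic_number, a.formal_charge, s)
        a.implicit_h = max(0, h - a.radical_electrons)
    return out


def verify_element(mol: Molecule) -> RejectionReason | None:
    """Step I: element and isotope validity.  Never modifies the molecule."""
    bad = []
    for i, a in enumerate(mol.atoms):
        if not 1 <= a.atomic_number <= tables.MAX_Z:
            bad.append(i)
        elif a.isotope_mass and not tables.is_valid_isotope(
                a.atomic_number, a.isotope_mass):
            bad.append(i)
    if bad:
        details = ", ".join(
            f"{mol.atoms[i].symbol}{mol.atoms[i].isotope_mass or ''}" for i in bad)
        return RejectionReason("verify_element",
                               f"invalid element/isotope: {details}", bad)
    return None


def _foldable_h(mol: Molecule, h: int) -> int | None:
    """Neighbor index if explicit hydrogen ``h`` may be made implicit."""
    a = mol.atoms[h]
    if a.formal_charge or a.isotope_mass or a.radical_electrons:
        return None
    nbrs = list(mol.neighbors(h))
    if len(nbrs) != 1:
        return None        # H2 partner has 1 bond, but see organic test below
    j, b = nbrs[0]
    if b.kind is not BondKind.COVALENT or b.order != 1:
        return None
    if b.wedge is not Wedge.NONE:
        return None
    nb = mol.atoms[j]
    if nb.atomic_number == 1:
        return None        # H2
    if classify_element(nb.atomic_number) is not ElementClass.ORGANIC:
        return None
    return j


def verify_hydrogen(mol: Molecule) -> Molecule:
    """Step II: explicit hydrogens folded to implicit counts, then the
    simplistic valence model's charge corrections for uncharged atoms.

    Explicit H in H2, H radicals, H+/H-, charged/isotopic H, H on wedge
    bonds and H not single-covalently bonded to an organic atom stay
    explicit.
    """
    out = mol.copy()
    drop: set[int] = set()
    for i, a in enumerate(out.atoms):
        if a.atomic_number != 1 or i in drop:
            continue
        j = _foldable_h(out, i)
        if j is None or j in drop:
            continue
        out.atoms[j].implicit_h += 1
        # preserve any tetrahedral reference through the folding
        st = out.atoms[j].tet_stereo
        if st is not None and i in st[0] and -1 not in st[0]:
            refs = tuple(-1 if r == i else r for r in st[0])
            out.atoms[j].tet_stereo = (refs, st[1])
        drop.add(i)
    if drop:
        out.remove_atoms(drop)

    halogens = {tables.atomic_number(s) for s in ("Cl", "Br", "I")}
    group15 = {tables.atomic_number(s) for s in ("N", "P", "As")}
    group16 = {tables.atomic_number(s) for s in ("S", "Se")}
    for i, a in enumerate(out.atoms):
        if a.formal_charge != 0:
            continue
        z = a.atomic_number
        v = atom_valence(out, i)
        if z in group15 and v == 5:
            if a.implicit_h >= 1:
                a.formal_charge = 1
                a.implicit_h -= 1
            else:
                log.info("valence-5 %s without implicit H left unchanged", a.symbol)
        elif z in group16 and v in (6, 4):
            if a.implicit_h >= 1:
                a.formal_charge = -1
                a.implicit_h -= 1
            else:
                log.info("valence-%d %s without implicit H left unchanged",
                         v, a.symbol)
        elif z in halogens and v in (3, 5, 7):
            if a.implicit_h >= 1:
                a.formal_charge = -1
                a.implicit_h -= 1
            else:
                log.info("hypervalent %s without implicit H left unchanged",
                         a.symbol)
    for i, a in enumerate(out.atoms):
        if a.atomic_number != 1 and \
                classify_element(a.atomic_number) is not ElementClass.ORGANIC:
            a.implicit_h = 0       # 'Li' does not become 'LiH'
    return out


def verify_functional_groups(mol: Molecule):
    """Step III: normalize nonstandard functional-group drawings.

    Returns ``(molecule, [TransformationRecord, ...])``.  Never rejects;
    chemically impossible outcomes surface in step IV.
    """
    from .transform import apply_all
    return apply_all(mol)


def verify_valence(mol: Molecule,
                   table: tables.ValenceTable | None = None) -> RejectionReason | None:
    """Step IV: every atom's configuration must be in the valence
    knowledgebase, with its implicit hydrogen count within the allowance.
    """
    table = table or tables.default_valence_table()
    bad = []
    for i, a in enumerate(mol.atoms):
        ns, npi = sigma_pi_counts(mol, i)
        if not table.allows(a.atomic_number, a.formal_charge, ns, npi,
                            a.implicit_h):
            bad.append(i)
    if bad:
        details = ", ".join(
            f"{mol.atoms[i].symbol}(q={mol.atoms[i].formal_charge},"
            f"v={atom_valence(mol, i)})" for i in bad)
        return RejectionReason("verify_valence",
                               f"disallowed valence configuration: {details}", bad)
    return None
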
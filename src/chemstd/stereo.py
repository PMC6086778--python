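"""Canonical stereocenter configuration (step VIII).

Eligibility of tetrahedral atoms and double bonds is decided from symmetry
classes (explicit hydrogens pinned to class 0); annotated parities are
reconciled with wedge annotations and coordinates; stereo annotation on
ineligible atoms/bonds is stripped.  Double bonds that are stereogenic but
unresolvable stay 'undefined' and are depicted as crossed double bonds.

Newly created stereocenters (e.g. by earlier normalization steps) are
marked undefined: the deposited data cannot define them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .mol import (BondKind, Molecule, Wedge, atom_valence, smallest_ring_size,
                  symmetry_classes)
from .tables import atomic_number

__all__ = [
    "StereoChangeRecord", "tetrahedral_eligibility", "resolve_tetrahedral",
    "double_bond_eligibility", "resolve_double_bond", "standardize_stereo",
]

_N = atomic_number("N")
_P = atomic_number("P")
_S = atomic_number("S")
_O = atomic_number("O")
_C = atomic_number("C")

COLLINEAR_TOL_DEG = 10.0


@dataclass
class StereoChangeRecord:
    added: int = 0
    modified: int = 0
    removed: int = 0
    unchanged: int = 0


def _coordination(mol: Molecule, i: int) -> int:
    return mol.degree(i) + mol.atoms[i].implicit_h


def _ox_type_neighbor(mol: Molecule, j: int, via) -> int | None:
    """Element of a mesomeric OH/O-/=O/SH/S-/=S ligand, else None.

    Only *like* ligands can swap by mesomerism: two O-type or two S-type
    ligands negate chirality (O=P-OH is achiral) whereas one of each does
    not (S=P-OH can be chiral), so callers count per element.
    """
    p = mol.atoms[j]
    if p.atomic_number not in (_O, _S):
        return None
    if mol.degree(j) != 1:
        return None
    if via.order == 2 or p.implicit_h >= 1 or p.formal_charge == -1:
        return p.atomic_number
    return None


def tetrahedral_eligibility(mol: Molecule, i: int, classes: list[int],
                            aromatic_atoms: set[int]) -> tuple[bool, str]:
    """(eligible, reason-if-not)."""
    a = mol.atoms[i]
    if i in aromatic_atoms:
        return False, "aromatic atom"
    if a.atomic_number == 1:
        return False, "hydrogen atom"
    if mol.total_h(i) > 1:
        return False, "more than one attached hydrogen"
    if a.atomic_number == _N and mol.total_h(i) > 0:
        return False, "nitrogen with attached hydrogen"
    v = atom_valence(mol, i)
    coord = _coordination(mol, i)
    kinds = [_ox_type_neighbor(mol, j, b) for j, b in mol.covalent_neighbors(i)]
    ox = max(kinds.count(_O), kinds.count(_S))   # like ligands only
    if a.atomic_number == _P:
        if not ((v == 3 and coord == 3) or (v == 5 and coord == 4)):
            return False, "phosphorus valence/coordination"
        if ox > 1:
            return False, "mesomeric O/S ligands on phosphorus"
    elif a.atomic_number == _S:
        if not ((v == 6 and coord == 4) or (v == 4 and coord == 3)):
            return False, "sulfur valence/coordination"
        if any(b.order not in (1, 2) for _, b in mol.covalent_neighbors(i)):
            return False, "sulfur with non single/double bond"
        if v == 6:
            for j, b in mol.covalent_neighbors(i):
                p = mol.atoms[j]
                if b.order == 1 and p.atomic_number == _C \
                        and (p.implicit_h > 0 or p.formal_charge):
                    return False, "sulfur next to CH/charged carbon"
        else:
            if ox > 1:
                return False, "mesomeric O/S ligands on sulfur"
    else:
        if not (v == 4 and coord == 4):
            return False, "not tetra-valent tetra-coordinated"
    nbr_classes = [classes[j] for j, _ in mol.covalent_neighbors(i)]
    nbr_classes += [0] * a.implicit_h
    if len(nbr_classes) != len(set(nbr_classes)):
        return False, "neighbors share a symmetry class"
    return True, ""


def _phantom(vectors):
    sx = [-sum(v[k] for v in vectors) for k in range(3)]
    return tuple(sx)


def _parity_from_positions(center, refs_pos) -> int | None:
    """1 (counterclockwise viewed from the first reference) or 2."""
    vs = [tuple(p[k] - center[k] for k in range(3)) for p in refs_pos]
    r2 = tuple(vs[1][k] - vs[0][k] for k in range(3))
    r3 = tuple(vs[2][k] - vs[0][k] for k in range(3))
    r4 = tuple(vs[3][k] - vs[0][k] for k in range(3))
    cx = (r3[1] * r4[2] - r3[2] * r4[1],
          r3[2] * r4[0] - r3[0] * r4[2],
          r3[0] * r4[1] - r3[1] * r4[0])
    det = sum(r2[k] * cx[k] for k in range(3))
    if abs(det) < 1e-9:
        return None
    return 1 if det < 0 else 2


def _derive_parity(mol: Molecule, i: int):
    """Parity from coordinates (3-D) or wedge pseudo-depth (2-D)."""
    a = mol.atoms[i]
    if a.coords is None:
        return None
    refs = sorted(j for j, _ in mol.covalent_neighbors(i))
    if a.implicit_h == 1:
        refs.append(-1)
    if len(refs) != 4:
        return None
    center = (a.coords + (0.0,) * 3)[:3]
    wedge_seen = False
    pos = []
    for r in refs:
        if r == -1:
            pos.append(None)
            continue
        p = mol.atoms[r].coords
        if p is None:
            return None
        p = (p + (0.0,) * 3)[:3]
        if mol.dimensionality != 3:
            b = mol.bond_between(i, r)
            zz = 0.0
            if b.wedge is not Wedge.NONE and b.a1 == i:
                zz = 1.0 if b.wedge is Wedge.UP else -1.0
                wedge_seen = True
            p = (p[0], p[1], zz)
        pos.append(p)
    if mol.dimensionality != 3 and not wedge_seen:
        return None
    known = [tuple(p[k] - center[k] for k in range(3))
             for p in pos if p is not None]
    for k, p in enumerate(pos):
        if p is None:
            ph = _phantom(known)
            pos[k] = tuple(center[m] + ph[m] for m in range(3))
    parity = _parity_from_positions(center, pos)
    if parity is None:
        return None
    return (tuple(refs), parity)


def resolve_tetrahedral(mol: Molecule, i: int):
    """Reconciled parity: annotated vs wedge/coordinate-derived.

    Returns a ``(refs, sense)`` pair or None for 'undefined'.  In 2-D a
    coordinate-derived parity needs wedge support, and an annotated parity
    contradicting the wedge-derived one yields 'undefined'.
    """
    ann = mol.atoms[i].tet_stereo
    der = _derive_parity(mol, i)
    if mol.dimensionality == 3:
        return der or ann
    if ann is not None and der is not None:
        return ann if _same_parity(ann, der) else None
    if ann is not None:
        return ann
    return der


def _same_parity(a, b) -> bool:
    from .smiles import _permutation_parity
    refs_a, sense_a = a
    refs_b, sense_b = b
    if sorted(refs_a) != sorted(refs_b):
        return False
    flip = _permutation_parity(tuple(refs_a), tuple(refs_b))
    return (sense_a if not flip else 3 - sense_a) == sense_b


# --------------------------------------------------------------------------
# Double bonds
# --------------------------------------------------------------------------


def double_bond_eligibility(mol: Molecule, b, classes: list[int],
                            aromatic_atoms: set[int]) -> str:
    """'eligible', 'undefined' (stereogenic but unresolvable) or
    'ineligible'."""
    if b.order != 2 or b.kind is not BondKind.COVALENT or b.aromatic:
        return "ineligible"
    a1, a2 = b.a1, b.a2
    if a1 in aromatic_atoms or a2 in aromatic_atoms:
        return "ineligible"
    for end in (a1, a2):
        if _coordination(mol, end) != 3:
            return "ineligible"
    ring = smallest_ring_size(mol, a1, a2)
    if ring and ring < 8:
        return "ineligible"
    for end in (a1, a2):
        if mol.total_h(end) >= 2:
            return "undefined"
    for end, other in ((a1, a2), (a2, a1)):
        if mol.atoms[end].atomic_number == _N:
            if mol.total_h(end) > 0:
                return "undefined"
            for j, nb in mol.covalent_neighbors(end):
                if j == other:
                    continue
                p = mol.atoms[j]
                if p.atomic_number == 1:
                    return "undefined"
                if p.atomic_number == _C:
                    if p.implicit_h > 0:
                        return "undefined"
                    if any(mol.atoms[k].atomic_number in (1, _C)
                           for k, _ in mol.covalent_neighbors(j) if k != end):
                        return "undefined"
                    if any(bb.order == 1 for k, bb in
                           mol.covalent_neighbors(j) if k != end):
                        return "undefined"
    for end, other in ((a1, a2), (a2, a1)):
        side = [classes[j] for j, _ in mol.covalent_neighbors(end)
                if j != other]
        side += [0] * mol.atoms[end].implicit_h
        if len(side) != len(set(side)):
            return "ineligible"
    return "eligible"


def _side_refs(mol: Molecule, b, classes: list[int]) -> tuple[int, int]:
    """Highest-symmetry-class explicit neighbor on each side."""
    refs = []
    for end, other in ((b.a1, b.a2), (b.a2, b.a1)):
        cand = [(classes[j], j) for j, _ in mol.covalent_neighbors(end)
                if j != other]
        refs.append(max(cand)[1] if cand else None)
    return tuple(refs)


def _angle_deg(v1, v2) -> float:
    dot = v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    if n1 * n2 == 0:
        return 0.0
    c = max(-1.0, min(1.0, dot / (n1 * n2)))
    return math.degrees(math.acos(c))


def resolve_double_bond(mol: Molecule, b, classes: list[int]):
    """E/Z (as a (ref1, ref2, 'cis'|'trans') triple) or 'undefined'.

    A deposited 'undefined' (crossed bond) always stays undefined; else an
    annotated parity wins; else geometry decides, with single bonds within
    10 degrees of collinear to the double-bond axis treated as undefined.
    """
    if b.db_stereo == "undefined" or b.crossed:
        return "undefined"
    r1, r2 = _side_refs(mol, b, classes)
    if r1 is None or r2 is None:
        return "undefined"
    if isinstance(b.db_stereo, tuple):
        return _rel_for_refs(mol, b, b.db_stereo, (r1, r2))
    # geometric perception
    c1 = mol.atoms[b.a1].coords
    c2 = mol.atoms[b.a2].coords
    p1 = mol.atoms[r1].coords
    p2 = mol.atoms[r2].coords
    if None in (c1, c2, p1, p2):
        return "undefined"
    c1, c2 = (c1 + (0.0,) * 3)[:3], (c2 + (0.0,) * 3)[:3]
    p1, p2 = (p1 + (0.0,) * 3)[:3], (p2 + (0.0,) * 3)[:3]
    axis = tuple(c2[k] - c1[k] for k in range(3))
    v1 = tuple(p1[k] - c1[k] for k in range(3))
    v2 = tuple(p2[k] - c2[k] for k in range(3))
    if abs(_angle_deg(v1, axis) - 180.0) <= COLLINEAR_TOL_DEG:
        return "undefined"
    rev_axis = tuple(-x for x in axis)
    if abs(_angle_deg(v2, rev_axis) - 180.0) <= COLLINEAR_TOL_DEG:
        return "undefined"
    # same side test via perpendicular components
    def perp(v, ax):
        n2 = sum(x * x for x in ax)
        t = sum(v[k] * ax[k] for k in range(3)) / n2
        return tuple(v[k] - t * ax[k] for k in range(3))
    q1, q2 = perp(v1, axis), perp(v2, axis)
    dot = sum(q1[k] * q2[k] for k in range(3))
    if abs(dot) < 1e-12:
        return "undefined"
    rel = "cis" if dot > 0 else "trans"
    return (r1, r2, rel)


def _rel_for_refs(mol: Molecule, b, stored: tuple, want: tuple):
    r1s, r2s, rel = stored
    flips = 0
    for end, other, rs, rw in ((b.a1, b.a2, r1s, want[0]),
                               (b.a2, b.a1, r2s, want[1])):
        if rs == rw:
            continue
        others = [j for j, _ in mol.covalent_neighbors(end) if j != other]
        if rs in others and rw in others:
            flips += 1
        else:
            return "undefined"
    if flips % 2:
        rel = "trans" if rel == "cis" else "cis"
    return (want[0], want[1], rel)


# --------------------------------------------------------------------------
# Driver
# --------------------------------------------------------------------------


def standardize_stereo(mol: Molecule) -> tuple[Molecule, StereoChangeRecord]:
    """Resolve every eligible stereocenter, strip annotation everywhere
    else, and count additions/modifications/removals."""
    out = mol.copy()
    classes = symmetry_classes(out)
    aromatic_atoms: set[int] = set()
    for b in out.bonds:
        if b.aromatic:
            aromatic_atoms |= {b.a1, b.a2}
    rec = StereoChangeRecord()

    for i, a in enumerate(out.atoms):
        had = a.tet_stereo is not None
        ok, _reason = tetrahedral_eligibility(out, i, classes, aromatic_atoms)
        if not ok:
            if had:
                rec.removed += 1
            a.tet_stereo = None
            for _, b in out.covalent_neighbors(i):
                if b.wedge is not Wedge.NONE and b.a1 == i:
                    b.wedge = Wedge.NONE
            continue
        resolved = resolve_tetrahedral(out, i)
        if resolved is None:
            if had:
                rec.removed += 1
            else:
                rec.added += 1          # new center, marked undefined
            a.tet_stereo = None
        else:
            if not had:
                rec.added += 1
            elif _same_parity(a.tet_stereo, resolved):
                rec.unchanged += 1
            else:
                rec.modified += 1
            a.tet_stereo = resolved

    for b in out.bonds:
        had = b.db_stereo is not None
        verdict = double_bond_eligibility(out, b, classes, aromatic_atoms) \
            if b.order == 2 and b.kind is BondKind.COVALENT else "ineligible"
        if verdict == "ineligible":
            if had:
                rec.removed += 1
            b.db_stereo = None
            b.crossed = False
            continue
        resolved = resolve_double_bond(out, b, classes) \
            if verdict == "eligible" else "undefined"
        if resolved == "undefined":
            if had and b.db_stereo != "undefined":
                rec.removed += 1
            elif not had:
                rec.added += 1
            b.db_stereo = "undefined"
            b.crossed = True
        else:
            if not had:
                rec.added += 1
            elif b.db_stereo == resolved:
                rec.unchanged += 1
            else:
                rec.modified += 1
            b.db_stereo = resolved
            b.crossed = False
    return out, rec
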
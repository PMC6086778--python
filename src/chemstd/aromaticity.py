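"""Aromaticity perception and canonical rekekulization.

Two perception models are provided:

* the *general* model — Hückel 4n+2 electron counting over conjugated ring
  systems assembled from the smallest-ring basis (rings and fused unions up
  to a combined path length of 40), with exocyclic double bonds not
  disqualifying a ring;
* the *ring-focused* model — alternating single/double six-membered rings
  only (the stricter MACCS-style count), used exclusively as a tautomer
  scoring criterion.

Rekekulization erases the single/double assignment inside perceived
aromatic systems and reassigns it by a backtracking perfect matching in
canonical bond order, so the output is deterministic and label-invariant
and succeeds whenever any Kekulé form exists.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import tables
from .mol import BondKind, Molecule, canonical_order, sssr

__all__ = [
    "AromaticityModel", "GENERAL", "RING_FOCUSED", "KekulizationError",
    "perceive_aromaticity", "kekulize_canonical", "clear_aromatic_flags",
    "ring_focused_aromatic_atoms", "match_pi_subgraph",
]


@dataclass(frozen=True)
class AromaticityModel:
    name: str
    max_ring_path: int = 40
    prune_exocyclic: bool = False


GENERAL = AromaticityModel("general", max_ring_path=40, prune_exocyclic=False)
RING_FOCUSED = AromaticityModel("ring_focused")


class KekulizationError(ValueError):
    """An aromatic system admits no Kekulé assignment."""


def clear_aromatic_flags(mol: Molecule) -> None:
    for b in mol.bonds:
        b.aromatic = False


# --------------------------------------------------------------------------
# Hückel electron counting
# --------------------------------------------------------------------------

_LONE_PAIR_DONORS = frozenset(
    tables.atomic_number(s) for s in ("N", "O", "S", "Se", "P", "As", "Te"))


def _pi_contribution(mol: Molecule, i: int, cycle: set[int]) -> int | None:
    """Electrons atom i donates to the pi system of ``cycle``; None = not sp2."""
    a = mol.atoms[i]
    n_double_in = n_double_out = n_triple = 0
    for j, b in mol.covalent_neighbors(i):
        if b.order == 3:
            n_triple += 1
        elif b.order == 2:
            if j in cycle:
                n_double_in += 1
            else:
                n_double_out += 1
    if n_triple or n_double_in > 1:
        return None
    if n_double_in:
        return 1
    if n_double_out:
        # exocyclic double bond: contributes no electrons but, with pruning
        # off, does not disqualify the ring either
        return 0
    z = a.atomic_number
    if z == tables.atomic_number("C"):
        if a.formal_charge < 0:
            return 2
        if a.formal_charge > 0:
            return 0
        return None  # saturated carbon breaks conjugation
    if z in _LONE_PAIR_DONORS:
        return 2
    if z == tables.atomic_number("B") and a.formal_charge == 0:
        return 0  # empty p orbital
    return None


def _cycle_aromatic(mol: Molecule, cycle: set[int]) -> bool:
    total = 0
    for i in cycle:
        c = _pi_contribution(mol, i, cycle)
        if c is None:
            return False
        total += c
    return total >= 2 and total % 4 == 2


def _ring_bonds(mol: Molecule, atoms: set[int]) -> list:
    out = []
    for b in mol.bonds:
        if b.kind is BondKind.COVALENT and b.a1 in atoms and b.a2 in atoms:
            out.append(b)
    return out


def perceive_aromaticity(mol: Molecule,
                         model: AromaticityModel = GENERAL) -> set[int]:
    """Set aromatic flags; returns the set of aromatic atom indices.

    Operates on concrete Kekulé bond orders.  Simple rings of the smallest
    ring basis are tested first, then unions of fused rings (envelope
    systems such as azulene's 10-membered perimeter), bounded by the
    model's maximum combined path length.
    """
    clear_aromatic_flags(mol)
    if model.name == "ring_focused":
        atoms = ring_focused_aromatic_atoms(mol)
    else:
        rings = [set(r) for r in sssr(mol)]
        rings = [r for r in rings if len(r) <= model.max_ring_path]
        atoms: set[int] = set()
        for r in rings:
            if _cycle_aromatic(mol, r):
                atoms |= r
        # fused unions: group rings sharing an edge, try cumulative unions
        groups: list[list[set[int]]] = []
        for r in rings:
            merged = None
            for g in groups:
                if any(len(r & other) >= 2 for other in g):
                    g.append(r)
                    merged = g
                    break
            if merged is None:
                groups.append([r])
        # iterate merging of groups that became connectable
        changed = True
        while changed:
            changed = False
            for x in range(len(groups)):
                for y in range(x + 1, len(groups)):
                    ax = set().union(*groups[x])
                    ay = set().union(*groups[y])
                    if len(ax & ay) >= 2:
                        groups[x].extend(groups[y])
                        del groups[y]
                        changed = True
                        break
                if changed:
                    break
        for g in groups:
            union = set().union(*g)
            if len(union) <= model.max_ring_path and not union <= atoms:
                if _cycle_aromatic(mol, union):
                    atoms |= union
    for b in _ring_bonds(mol, atoms):
        # flag only bonds that lie in some ring of the aromatic set
        b.aromatic = True
    # drop flags on bonds that are mere bridges between aromatic systems
    ring_edge = set()
    for r in sssr(mol):
        rs = set(r)
        for b in _ring_bonds(mol, rs):
            ring_edge.add((min(b.a1, b.a2), max(b.a1, b.a2)))
    for b in mol.bonds:
        if b.aromatic and (min(b.a1, b.a2), max(b.a1, b.a2)) not in ring_edge:
            b.aromatic = False
    return atoms


def ring_focused_aromatic_atoms(mol: Molecule) -> set[int]:
    """Atoms of six-membered rings with alternating single/double bonds."""
    out: set[int] = set()
    for ring in sssr(mol):
        if len(ring) != 6:
            continue
        cyc = _order_cycle(mol, ring)
        if cyc is None:
            continue
        orders = []
        ok = True
        for k in range(6):
            b = mol.bond_between(cyc[k], cyc[(k + 1) % 6])
            if b is None or b.kind is not BondKind.COVALENT:
                ok = False
                break
            orders.append(b.order)
        if ok and all(o in (1, 2) for o in orders):
            if all(orders[k] != orders[(k + 1) % 6] for k in range(6)):
                out |= set(cyc)
    return out


def _order_cycle(mol: Molecule, ring: list[int]) -> list[int] | None:
    """Arrange a ring atom set into traversal order."""
    rs = set(ring)
    start = min(ring)
    cyc = [start]
    prev = None
    cur = start
    for _ in range(len(ring) - 1):
        nxt = None
        for j, b in mol.covalent_neighbors(cur):
            if j in rs and j != prev and j not in cyc:
                nxt = j
                break
        if nxt is None:
            return None
        cyc.append(nxt)
        prev, cur = cur, nxt
    if mol.bond_between(cyc[-1], start) is None:
        return None
    return cyc


# --------------------------------------------------------------------------
# Kekulization
# --------------------------------------------------------------------------


def _pi_need(mol: Molecule, i: int, erased: set[tuple[int, int]]) -> int:
    """Whether atom i must receive one double bond within the erased system."""
    a = mol.atoms[i]
    dv_candidates = tables._DEFAULT_VALENCES.get((a.atomic_number, a.formal_charge))
    if not dv_candidates:
        return 0
    # bond-order sum counting erased bonds as single
    s = a.implicit_h
    for j, b in mol.covalent_neighbors(i):
        key = (min(i, j), max(i, j))
        s += 1 if key in erased else b.order
    for dv in dv_candidates:
        if s <= dv:
            return min(dv - s, 1)
    return 0


def match_pi_subgraph(needy: list[int], edges: list[tuple[int, int]]) -> set[tuple[int, int]] | None:
    """Perfect matching covering every needy atom, via ordered backtracking.

    ``edges`` must be listed in the deterministic order to try; returns the
    chosen set of matched edges or None if no cover exists.
    """
    need = set(needy)
    adj: dict[int, list[int]] = {i: [] for i in need}
    for u, v in edges:
        if u in need and v in need:
            adj[u].append(v)
            adj[v].append(u)

    order = list(needy)
    matched: dict[int, int] = {}

    def bt(k: int) -> bool:
        while k < len(order) and order[k] in matched:
            k += 1
        if k == len(order):
            return True
        u = order[k]
        for v in adj[u]:
            if v not in matched:
                matched[u] = v
                matched[v] = u
                if bt(k + 1):
                    return True
                del matched[u]
                del matched[v]
        return False

    if not bt(0):
        return None
    return {(min(u, v), max(u, v)) for u, v in matched.items()}


def kekulize_canonical(mol: Molecule) -> Molecule:
    """Canonical Kekulé form: perceive, erase, reassign in canonical order.

    Aromatic systems are re-derived from the current bond orders with the
    general model; the single/double assignment inside them is erased and
    re-made by perfect matching, trying bonds in canonical order so the
    result is label-invariant.  Aromatic flags remain as annotation.
    Structures with fewer than three atoms are returned unchanged.
    """
    if len(mol.atoms) < 3:
        return mol
    out = mol.copy()
    arom_atoms = perceive_aromaticity(out, GENERAL)
    if not arom_atoms:
        return out
    rank = canonical_order(out)
    erased: set[tuple[int, int]] = set()
    for b in out.bonds:
        if b.aromatic:
            erased.add((min(b.a1, b.a2), max(b.a1, b.a2)))
    needy = [i for i in arom_atoms if _pi_need(out, i, erased)]
    edges = sorted(erased, key=lambda e: sorted((rank[e[0]], rank[e[1]])))
    # order each edge's endpoints canonically for the matcher's scan order
    matching = match_pi_subgraph(sorted(needy, key=lambda i: rank[i]), edges)
    if matching is None:
        raise KekulizationError(
            f"no Kekulé assignment for aromatic system of {len(needy)} atoms")
    for b in out.bonds:
        key = (min(b.a1, b.a2), max(b.a1, b.a2))
        if key in erased:
            b.order = 2 if key in matching else 1
    return out
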
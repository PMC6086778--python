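"""Canonical tautomer selection (valence-bond canonicalization, step VI).

Protons and charges are treated as mobile: tautomers are enumerated per
covalently-connected component by 1,3- and 1,5-proton shifts along
alternating single/double bond paths plus 1,3-charge shifts, in a
breadth-first canonic walk from a canonically relabeled starting state, so
the emission order is independent of input atom numbering.  Methyl and
methylene groups never donate protons.

Generation is bounded: components on the blacklist skip the step entirely;
components on the limit list are capped at 2,500 generated tautomers,
everything else at 250,000.  No tautomer of a less preferred energetic
class than the input is generated, and tautomers whose immobilized-charge
pattern differs from the input's are never produced.

Selection is greedy under a strict lexicographic score; if the best
enumerated tautomer does not beat the original, a final arbitration on
``count(C=C) - 2*count(N=N)`` decides, and ties keep the original.  The
result must pass the valence knowledgebase and must not contain adjacent
like charges, otherwise the record is rejected at this step.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from . import tables
from .mol import (BondKind, Molecule, atom_valence, canonical_order,
                  covalent_components, sssr)
from .smiles import read_smiles, write_canonical_smiles
from .tables import atomic_number
from .verify import RejectionReason

__all__ = [
    "UNLIMITED_CAP", "LIMITED_CAP", "TautomerConfig", "energetic_class",
    "immobilized_charges", "check_lists", "enumerate_tautomers",
    "score_state", "prefer", "canonical_tautomer", "standardize_valence_bond",
    "load_smiles_list",
]

UNLIMITED_CAP = 250_000
LIMITED_CAP = 2_500

_C = atomic_number("C")
_N = atomic_number("N")
_O = atomic_number("O")
_P = atomic_number("P")
_S = atomic_number("S")

_MOBILE = (_C, _N, _O, _P, _S)
# Protons never move onto carbon: acidic C-H normalization (keto-enol and
# friends) is deliberately not performed.  Carbon may still *donate* its
# single methine hydrogen.
_ACCEPTORS = (_N, _O, _P, _S)

_PREFERRED_VALENCE = {_C: 4, _N: 3, _P: 3, _O: 2, _S: 2}


@dataclass
class TautomerConfig:
    cap: int = UNLIMITED_CAP
    limited_cap: int = LIMITED_CAP
    blacklist: frozenset = frozenset()
    limitlist: frozenset = frozenset()


def load_smiles_list(stream) -> frozenset:
    """Load a one-SMILES-per-line list as a set of canonical keys."""
    keys = set()
    for line in stream:
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        keys.add(write_canonical_smiles(read_smiles(line)))
    return frozenset(keys)


# --------------------------------------------------------------------------
# Energetic classes and immobilized charges
# --------------------------------------------------------------------------


def energetic_class(zs, charges) -> int:
    """Charged-atom-pattern class, 1 (least preferred) .. 7 (best)."""
    c_pos = c_neg = False
    any_pos = any_neg = False   # restricted to N, O, S, P, C
    o_pos = n_neg = n_pos = o_neg = False
    for z, q in zip(zs, charges):
        if q == 0:
            continue
        if z == _C:
            c_pos |= q > 0
            c_neg |= q < 0
        if z in _MOBILE:
            any_pos |= q > 0
            any_neg |= q < 0
        if z == _O:
            o_pos |= q > 0
            o_neg |= q < 0
        if z == _N:
            n_neg |= q < 0
            n_pos |= q > 0
    if c_pos and c_neg:
        return 1
    if any_pos and any_neg:
        return 2
    if c_pos or c_neg:
        return 3
    if o_pos:
        return 4
    if n_neg:
        return 5
    if n_pos or o_neg:
        return 6
    return 7


def immobilized_charges(mol: Molecule) -> set[tuple[int, int]]:
    """(atom index, required charge) pairs the walk must not alter.

    Covers charged atoms in ionic/complex bonds, the terminal N(-) of
    azide-like [N-]=[N+]=* groups, and the O(-)/S(-) of nitro-like groups.
    """
    out: set[tuple[int, int]] = set()
    for b in mol.bonds:
        if b.kind in (BondKind.IONIC, BondKind.COMPLEX):
            for i in (b.a1, b.a2):
                if mol.atoms[i].formal_charge:
                    out.add((i, mol.atoms[i].formal_charge))
    for i, a in enumerate(mol.atoms):
        if a.atomic_number != _N or a.formal_charge != 1:
            continue
        if atom_valence(mol, i) != 4:
            continue
        deg = mol.degree(i)
        if deg == 2:
            for j, b in mol.covalent_neighbors(i):
                pj = mol.atoms[j]
                if b.order == 2 and pj.atomic_number == _N \
                        and pj.formal_charge == -1 and mol.degree(j) == 1:
                    out.add((j, -1))
        elif deg == 3:
            has_chalc_double = any(
                b.order == 2 and mol.atoms[j].atomic_number in (_O, _S)
                for j, b in mol.covalent_neighbors(i))
            if has_chalc_double:
                for j, b in mol.covalent_neighbors(i):
                    pj = mol.atoms[j]
                    if pj.atomic_number in (_O, _S) and pj.formal_charge == -1 \
                            and mol.degree(j) == 1:
                        out.add((j, -1))
    return out


def check_lists(component_key: str, config: TautomerConfig) -> str:
    """'skip' (blacklist), 'limited' (limit list) or 'unlimited'."""
    if component_key in config.blacklist:
        return "skip"
    if component_key in config.limitlist:
        return "limited"
    return "unlimited"


# --------------------------------------------------------------------------
# State-space walk
# --------------------------------------------------------------------------


class _Walk:
    """Breadth-first tautomer walk on a canonically labeled component."""

    def __init__(self, comp: Molecule, immobilized: set[tuple[int, int]]):
        self.mol = comp
        self.n = len(comp.atoms)
        self.zs = tuple(a.atomic_number for a in comp.atoms)
        self.frozen = {i for i, _ in immobilized}
        self.bond_key: dict[tuple[int, int], int] = {}
        self.adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n)]
        for bi, b in enumerate(comp.bonds):
            if b.kind is not BondKind.COVALENT:
                continue
            self.bond_key[(b.a1, b.a2)] = bi
            self.bond_key[(b.a2, b.a1)] = bi
            self.adj[b.a1].append((b.a2, bi))
            self.adj[b.a2].append((b.a1, bi))
        for lst in self.adj:
            lst.sort()
        self.start = (
            tuple(b.order for b in comp.bonds),
            tuple(a.implicit_h for a in comp.atoms),
            tuple(a.formal_charge for a in comp.atoms),
        )
        self.min_class = energetic_class(self.zs, self.start[2])

    # donors: heteroatoms with H, or carbon with exactly one hydrogen
    def _may_donate(self, z: int, h: int) -> bool:
        if h < 1:
            return False
        if z == _C:
            return h == 1      # no methyl/methylene tautomerization
        return z in (_N, _O, _S, _P)

    def successors(self, state):
        orders, hs, charges = state
        out = []
        for x in range(self.n):
            if self._may_donate(self.zs[x], hs[x]):
                for y, bxy in self.adj[x]:
                    if orders[bxy] != 1:
                        continue
                    for z_, byz in self.adj[y]:
                        if z_ == x or orders[byz] != 2:
                            continue
                        if self.zs[z_] in _ACCEPTORS:
                            no = list(orders)
                            no[bxy] = 2
                            no[byz] = 1
                            nh = list(hs)
                            nh[x] -= 1
                            nh[z_] += 1
                            out.append((tuple(no), tuple(nh), charges))
                        # extend to a 1,5-shift
                        for w, bzw in self.adj[z_]:
                            if w in (x, y) or orders[bzw] != 1:
                                continue
                            for v, bwv in self.adj[w]:
                                if v in (x, y, z_) or orders[bwv] != 2:
                                    continue
                                if self.zs[v] not in _ACCEPTORS:
                                    continue
                                no = list(orders)
                                no[bxy] = 2
                                no[byz] = 1
                                no[bzw] = 2
                                no[bwv] = 1
                                nh = list(hs)
                                nh[x] -= 1
                                nh[v] += 1
                                out.append((tuple(no), tuple(nh), charges))
            q = charges[x]
            if q in (-1, 1) and x not in self.frozen \
                    and self.zs[x] in _MOBILE:
                for y, bxy in self.adj[x]:
                    if orders[bxy] != 1:
                        continue
                    for z_, byz in self.adj[y]:
                        if z_ == x or orders[byz] != 2:
                            continue
                        if charges[z_] != 0 or z_ in self.frozen:
                            continue
                        if self.zs[z_] not in _MOBILE:
                            continue
                        no = list(orders)
                        no[bxy] = 2
                        no[byz] = 1
                        nq = list(charges)
                        nq[x] = 0
                        nq[z_] = q
                        out.append((tuple(no), hs, tuple(nq)))
        return out

    def run(self, cap: int):
        """Yield generated states in BFS order, up to ``cap``.

        The boolean attribute ``truncated`` reports whether the cap cut
        the walk short.
        """
        self.truncated = False
        seen = {self.start}
        queue = deque([self.start])
        emitted = 0
        while queue:
            state = queue.popleft()
            for nxt in self.successors(state):
                if nxt in seen:
                    continue
                if energetic_class(self.zs, nxt[2]) < self.min_class:
                    continue
                seen.add(nxt)
                emitted += 1
                yield nxt
                if emitted >= cap:
                    self.truncated = True
                    return
                queue.append(nxt)


def _component_submol(mol: Molecule, atoms: list[int]) -> tuple[Molecule, list[int]]:
    sub = Molecule()
    order = sorted(atoms)
    remap = {a: k for k, a in enumerate(order)}
    for a in order:
        sub.add_atom(mol.atoms[a].copy())
    for b in mol.bonds:
        if b.kind is BondKind.COVALENT and b.a1 in remap and b.a2 in remap:
            nb = b.copy()
            nb.a1, nb.a2 = remap[b.a1], remap[b.a2]
            nb.wedge = nb.wedge
            sub.add_bond(nb)
    return sub, order


def enumerate_tautomers(comp: Molecule, cap: int = UNLIMITED_CAP,
                        immobilized: set[tuple[int, int]] | None = None):
    """Generate tautomer states of a single component (BFS order).

    The component is relabeled canonically first, making the stream
    independent of the input atom numbering.  Each emitted state is a
    ``Molecule``; molecular formula (including total H) and net charge are
    conserved.  Components with fewer than two connected atoms yield
    nothing.
    """
    if len(comp.atoms) < 2 or not comp.bonds:
        return
    rank = canonical_order(comp)
    canon = comp.permuted(rank)
    immob = set()
    if immobilized:
        immob = {(rank[i], q) for i, q in immobilized}
    walk = _Walk(canon, immob)
    for orders, hs, charges in walk.run(cap):
        yield _apply_state(canon, (orders, hs, charges))


def _apply_state(canon: Molecule, state) -> Molecule:
    orders, hs, charges = state
    m = canon.copy()
    for bi, b in enumerate(m.bonds):
        b.order = orders[bi]
    for i, a in enumerate(m.atoms):
        a.implicit_h = hs[i]
        a.formal_charge = charges[i]
    return m


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TautomerScore:
    """Ordered criterion vector; comparison is strictly lexicographic."""
    key: tuple

    def __lt__(self, other: "TautomerScore") -> bool:
        return self.key < other.key


def score_state(walk_or_mol, state=None, rings6=None, ring_atoms=None) -> TautomerScore:
    """Score a tautomer (smaller = preferred).

    Accepts either a Molecule, or a ``_Walk`` plus a raw state for speed in
    long enumerations.
    """
    if state is None:
        mol: Molecule = walk_or_mol
        zs = [a.atomic_number for a in mol.atoms]
        hs = [a.implicit_h for a in mol.atoms]
        charges = [a.formal_charge for a in mol.atoms]
        bonds = [(b.a1, b.a2, b.order) for b in mol.bonds
                 if b.kind is BondKind.COVALENT]
        base = mol
    else:
        walk: _Walk = walk_or_mol
        orders, hs, charges = state
        zs = walk.zs
        bonds = [(b.a1, b.a2, orders[bi]) for bi, b in enumerate(walk.mol.bonds)
                 if b.kind is BondKind.COVALENT]
        base = walk.mol
    if rings6 is None:
        rings6 = _six_rings(base)
    if ring_atoms is None:
        ring_atoms = set()
        for r in sssr(base):
            ring_atoms |= set(r)

    valence = [0] * len(zs)
    for a1, a2, o in bonds:
        valence[a1] += o
        valence[a2] += o
    for i, h in enumerate(hs):
        valence[i] += h

    vp = 0
    for i, z in enumerate(zs):
        pref = _PREFERRED_VALENCE.get(z)
        if pref is not None:
            vp += pref - (valence[i] + abs(charges[i]))

    n_charged = sum(1 for q in charges if q)

    def cnt(zz, sign):
        return sum(1 for i, z in enumerate(zs)
                   if z == zz and (charges[i] > 0 if sign > 0 else charges[i] < 0))

    h_on = {z: 0 for z in (_C, _O, _S, _N, _P)}
    for i, z in enumerate(zs):
        if z in h_on:
            h_on[z] += hs[i]
    h_ring = sum(hs[i] for i in ring_atoms)

    cc_double = sum(1 for a1, a2, o in bonds
                    if o == 2 and zs[a1] == _C and zs[a2] == _C)

    zwit = _zwitterion_count(zs, charges, bonds, valence)
    arom = _ring_focused_count(rings6, {(min(a, b), max(a, b)): o
                                        for a, b, o in bonds})

    key = (
        vp,
        n_charged,
        cnt(_C, +1), cnt(_C, -1), cnt(_P, -1), cnt(_S, +1), cnt(_O, +1),
        cnt(_N, -1),
        -cnt(_N, +1), -cnt(_O, -1), -cnt(_S, -1), -cnt(_P, +1),
        -zwit,
        -h_on[_C],
        h_on[_O], h_on[_S],
        -arom,
        h_on[_N], h_on[_P],
        h_ring,
        cc_double,
    )
    return TautomerScore(key)


def _zwitterion_count(zs, charges, bonds, valence) -> int:
    adj: dict[int, list[tuple[int, int]]] = {}
    for a1, a2, o in bonds:
        adj.setdefault(a1, []).append((a2, o))
        adj.setdefault(a2, []).append((a1, o))
    n = 0
    for i, z in enumerate(zs):
        if z != _N or charges[i] != 1:
            continue
        if valence[i] == 4:
            for j, o in adj.get(i, ()):
                if o == 1 and zs[j] == _O and charges[j] == -1:
                    n += 1
            doubles = [j for j, o in adj.get(i, ()) if o == 2]
            if len(doubles) == 2:
                if any(zs[j] == _N and charges[j] == -1 for j in doubles):
                    n += 1
    return n


def _six_rings(mol: Molecule):
    """6-membered rings as bond-key cycles, precomputed once per topology."""
    from .aromaticity import _order_cycle
    out = []
    for ring in sssr(mol):
        if len(ring) != 6:
            continue
        cyc = _order_cycle(mol, ring)
        if cyc is None:
            continue
        out.append([(min(cyc[k], cyc[(k + 1) % 6]),
                     max(cyc[k], cyc[(k + 1) % 6])) for k in range(6)])
    return out


def _ring_focused_count(rings6, order_of: dict) -> int:
    atoms = 0
    for keys in rings6:
        orders = [order_of.get(k) for k in keys]
        if None in orders or any(o not in (1, 2) for o in orders):
            continue
        if all(orders[k] != orders[(k + 1) % 6] for k in range(6)):
            atoms += 6
    return atoms


def prefer(a: TautomerScore, b: TautomerScore) -> bool:
    """True iff score ``a`` is strictly preferred over ``b``."""
    return a.key < b.key


# --------------------------------------------------------------------------
# Selection driver
# --------------------------------------------------------------------------


@dataclass
class ComponentOutcome:
    n_generated: int = 0
    truncated: bool = False
    skipped: bool = False
    modified: bool = False


def canonical_tautomer(comp: Molecule, cap: int = UNLIMITED_CAP,
                       immobilized: set[tuple[int, int]] | None = None
                       ) -> tuple[Molecule, ComponentOutcome]:
    """Greedy best tautomer of one component versus its original form.

    Returns the chosen component (the original object if unchanged) plus
    bookkeeping.  Post-checks (valence, adjacent like charges) are the
    caller's responsibility: they apply to the whole structure.
    """
    outcome = ComponentOutcome()
    if len(comp.atoms) < 2 or not comp.bonds:
        outcome.skipped = True
        return comp, outcome
    rank = canonical_order(comp)
    canon = comp.permuted(rank)
    immob = {(rank[i], q) for i, q in (immobilized or set())}
    walk = _Walk(canon, immob)
    rings6 = _six_rings(canon)
    ring_atoms: set[int] = set()
    for r in sssr(canon):
        ring_atoms |= set(r)
    orig_score = score_state(walk, walk.start, rings6, ring_atoms)
    best_state = None
    best_score = None
    for st in walk.run(cap):
        outcome.n_generated += 1
        sc = score_state(walk, st, rings6, ring_atoms)
        if best_score is None or prefer(sc, best_score):
            best_state, best_score = st, sc
    outcome.truncated = getattr(walk, "truncated", False)
    if best_state is None:
        return comp, outcome
    chosen = None
    if prefer(best_score, orig_score):
        chosen = best_state
    else:
        # arbitration on count(C=C) - 2*count(N=N); lower wins
        if _arbitration(walk, best_state) < _arbitration(walk, walk.start):
            chosen = best_state
    if chosen is None:
        return comp, outcome
    outcome.modified = True
    return _apply_state(canon, chosen), outcome


def _arbitration(walk: _Walk, state) -> int:
    orders, _, _ = state
    cc = nn = 0
    for bi, b in enumerate(walk.mol.bonds):
        if orders[bi] != 2:
            continue
        z1, z2 = walk.zs[b.a1], walk.zs[b.a2]
        if z1 == _C and z2 == _C:
            cc += 1
        elif z1 == _N and z2 == _N:
            nn += 1
    return cc - 2 * nn


def adjacent_like_charges(mol: Molecule) -> list[int]:
    """Atoms involved in covalently bonded like-charge pairs."""
    bad: set[int] = set()
    for b in mol.bonds:
        if b.kind is not BondKind.COVALENT:
            continue
        q1 = mol.atoms[b.a1].formal_charge
        q2 = mol.atoms[b.a2].formal_charge
        if q1 and q2 and (q1 > 0) == (q2 > 0):
            bad |= {b.a1, b.a2}
    return sorted(bad)


def standardize_valence_bond(mol: Molecule, config: TautomerConfig | None = None):
    """Step VI over a whole structure: per-component canonical tautomers,
    then the valence and adjacent-like-charge post-checks.

    Returns ``(molecule, info)`` or a :class:`RejectionReason`.  ``info``
    maps component index -> :class:`ComponentOutcome`.
    """
    config = config or TautomerConfig()
    out = mol.copy()
    immob_full = immobilized_charges(out)
    info: dict[int, ComponentOutcome] = {}
    for ci, atoms in enumerate(covalent_components(out)):
        if len(atoms) < 2:
            info[ci] = ComponentOutcome(skipped=True)
            continue
        sub, order = _component_submol(out, sorted(atoms))
        back = {k: a for k, a in enumerate(order)}
        key = write_canonical_smiles(sub)
        mode = check_lists(key, config)
        if mode == "skip":
            info[ci] = ComponentOutcome(skipped=True)
            continue
        cap = config.limited_cap if mode == "limited" else config.cap
        immob_sub = {(order.index(i), q) for i, q in immob_full
                     if i in set(order)}
        chosen, outcome = canonical_tautomer(sub, cap, immob_sub)
        info[ci] = outcome
        if outcome.modified:
            _write_back(out, chosen, back)
    rej = _post_checks(out)
    if rej is not None:
        return rej
    return out, info


def _write_back(mol: Molecule, comp: Molecule, back: dict[int, int]) -> None:
    # component atoms come back canonically relabeled; recover positions by
    # matching the canonical ranks of the submolecule ordering
    # comp = submol.permuted(rank)  => comp atom r corresponds to submol
    # atom with rank[k] == r
    sub_indices = [back[k] for k in sorted(back)]
    # reconstruct rank from comp provenance: canonical_order of the submol
    sub, _ = _component_submol(mol, sub_indices)
    rank = canonical_order(sub)
    for k, r in enumerate(rank):
        orig = sub_indices[k]
        mol.atoms[orig].implicit_h = comp.atoms[r].implicit_h
        mol.atoms[orig].formal_charge = comp.atoms[r].formal_charge
    for b in sub.bonds:
        rb = comp.bond_between(rank[b.a1], rank[b.a2])
        ob = mol.bond_between(sub_indices[b.a1], sub_indices[b.a2])
        ob.order = rb.order


def _post_checks(mol: Molecule) -> RejectionReason | None:
    from .verify import verify_valence
    rej = verify_valence(mol)
    if rej is not None:
        return RejectionReason("standardize_valence_bond", rej.message,
                               rej.atom_indices)
    bad = adjacent_like_charges(mol)
    if bad:
        return RejectionReason(
            "standardize_valence_bond",
            "adjacent atoms with identical charge type", bad)
    return None
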
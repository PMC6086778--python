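"""SMILES reading and canonical isomeric SMILES writing.

The writer emits a *canonical* string: atom output order follows the
molecule's canonical ranking, so the string is independent of input atom
numbering.  ``dearomatize=True`` (the default for tracking keys) ignores
aromatic flags and writes concrete Kekulé bond orders; ``isomeric=True``
includes tetrahedral parity (``@``/``@@``), double-bond configuration
(``/``, ``\\``) and isotopes.  Nonstandard (ionic/complex/dative) bonds are
zero-order and never expressed: atoms joined only by them appear as
separate dot-components.

The reader accepts aromatic (lowercase) input and rekekulizes it by perfect
matching; aromatic input with no valid Kekulé assignment is a
:class:`~chemstd.aromaticity.KekulizationError`.
"""

from __future__ import annotations

import sys

from . import tables
from .aromaticity import KekulizationError, match_pi_subgraph
from .mol import Atom, Bond, BondKind, Molecule, canonical_order
from .tables import atomic_number, default_implicit_hydrogens

__all__ = ["SmilesError", "read_smiles", "write_canonical_smiles"]

_ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_AROMATIC_TOKENS = {"b": "B", "c": "C", "n": "N", "o": "O", "p": "P", "s": "S",
                    "se": "Se", "as": "As", "te": "Te"}


class SmilesError(ValueError):
    """Grammar or semantic error in a SMILES string."""


# --------------------------------------------------------------------------
# Reader
# --------------------------------------------------------------------------


class _RingSlot:
    __slots__ = ("atom", "order", "aromatic", "direction")

    def __init__(self, atom, order, aromatic, direction):
        self.atom = atom
        self.order = order
        self.aromatic = aromatic
        self.direction = direction


def read_smiles(s: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Implicit hydrogens on bare organic-subset atoms are filled with the
    default valence model after (re)kekulization of aromatic input; bracket
    atoms pin their hydrogen count.
    """
    mol = Molecule()
    aromatic_atoms: set[int] = set()
    # chiral bookkeeping: per atom, ordered neighbor refs (-1 = implicit H)
    nbr_order: dict[int, list[int]] = {}
    chirality: dict[int, int] = {}       # atom -> 1 (@) or 2 (@@)
    directional: list[tuple[int, int, str]] = []   # (u, v, char), u written first
    arom_bonds: set[int] = set()

    stack: list[int] = []
    prev: int | None = None
    pend_order: int | None = None
    pend_arom = False
    pend_dir: str | None = None
    rings: dict[int, _RingSlot] = {}

    i, n = 0, len(s)

    def add_bond(a, b, order, aromatic, direction, ring=False):
        bd = Bond(a, b, order=order)
        bd.aromatic = aromatic
        bi = mol.add_bond(bd)
        if aromatic:
            arom_bonds.add(bi)
        if direction:
            directional.append((a, b, direction))
        return bi

    def new_atom(atom: Atom, aromatic: bool, h_in_order: bool):
        nonlocal prev, pend_order, pend_arom, pend_dir
        idx = mol.add_atom(atom)
        nbr_order[idx] = []
        if aromatic:
            aromatic_atoms.add(idx)
        if prev is not None:
            if pend_order is None and not pend_arom:
                arom = aromatic and prev in aromatic_atoms
                add_bond(prev, idx, 1, arom, pend_dir)
            else:
                add_bond(prev, idx, pend_order or 1, pend_arom, pend_dir)
            nbr_order[idx].append(prev)
            nbr_order[prev].append(idx)
        if h_in_order:
            nbr_order[idx].append(-1)
        prev = idx
        pend_order, pend_arom, pend_dir = None, False, None
        return idx

    while i < n:
        c = s[i]
        if c in "-=#:/\\":
            if c in "-=#:" and pend_order is not None:
                raise SmilesError(f"conflicting bond symbols at position {i}")
            if c == "-":
                pend_order = 1
            elif c == "=":
                pend_order = 2
            elif c == "#":
                pend_order = 3
            elif c == ":":
                pend_order, pend_arom = 1, True
            else:
                pend_dir = c
                if pend_order is None:
                    pend_order = 1
            i += 1
        elif c == "(":
            if prev is None:
                raise SmilesError("branch with no preceding atom")
            stack.append(prev)
            i += 1
        elif c == ")":
            if not stack:
                raise SmilesError("unmatched ')'")
            prev = stack.pop()
            i += 1
        elif c == ".":
            prev = None
            pend_order, pend_arom, pend_dir = None, False, None
            i += 1
        elif c.isdigit() or c == "%":
            if prev is None:
                raise SmilesError("ring closure with no preceding atom")
            if c == "%":
                if i + 2 >= n + 1 or not s[i + 1:i + 3].isdigit():
                    raise SmilesError("bad %nn ring closure")
                num = int(s[i + 1:i + 3])
                i += 3
            else:
                num = int(c)
                i += 1
            if num in rings:
                slot = rings.pop(num)
                if slot.atom == prev:
                    raise SmilesError("ring closure to itself")
                order = slot.order if slot.order is not None else pend_order
                arom = slot.aromatic or pend_arom
                if order is None and not arom:
                    arom = slot.atom in aromatic_atoms and prev in aromatic_atoms
                direction = slot.direction
                if pend_dir:
                    # direction at second site is from closing atom's view
                    flipped = "/" if pend_dir == "\\" else "\\"
                    if direction and direction != flipped:
                        raise SmilesError("conflicting ring-bond directions")
                    direction = flipped
                add_bond(slot.atom, prev, order or 1, arom, direction, ring=True)
                # fill the reserved positions in both atoms' neighbor order
                no = nbr_order[slot.atom]
                no[no.index(-2 - num)] = prev
                nbr_order[prev].append(slot.atom)
            else:
                rings[num] = _RingSlot(prev, pend_order, pend_arom, pend_dir)
                nbr_order[prev].append(-2 - num)   # placeholder
            pend_order, pend_arom, pend_dir = None, False, None
        elif c == "[":
            j = s.find("]", i)
            if j < 0:
                raise SmilesError("unterminated bracket atom")
            atom, aromatic, chir, h_first = _parse_bracket(s[i + 1:j])
            idx = new_atom(atom, aromatic, h_first)
            if chir:
                chirality[idx] = chir
            i = j + 1
        elif c.isalpha() or c == "*":
            sym = None
            if c == "*":
                raise SmilesError("wildcard atoms not supported")
            if i + 1 < n and s[i:i + 2] in ("Cl", "Br"):
                sym = s[i:i + 2]
                i += 2
                aromatic = False
            elif i + 1 < n and s[i:i + 2] in ("se", "as", "te"):
                sym = _AROMATIC_TOKENS[s[i:i + 2]]
                i += 2
                aromatic = True
            elif c in _AROMATIC_TOKENS:
                sym = _AROMATIC_TOKENS[c]
                aromatic = True
                i += 1
            elif c.upper() in _ORGANIC_SUBSET and c.isupper():
                sym = c
                aromatic = False
                i += 1
            else:
                raise SmilesError(f"unexpected atom symbol at {i}: {c!r}")
            new_atom(Atom(atomic_number(sym)), aromatic, False)
        elif c.isspace():
            break
        else:
            raise SmilesError(f"unexpected character {c!r} at position {i}")

    if rings:
        raise SmilesError(f"unclosed ring bond(s): {sorted(rings)}")
    if stack:
        raise SmilesError("unclosed branch")

    _kekulize_input(mol, aromatic_atoms, arom_bonds)
    _fill_implicit_h(mol)
    _apply_chirality(mol, chirality, nbr_order)
    _apply_directions(mol, directional)
    return mol


def _parse_bracket(body: str):
    i, n = 0, len(body)
    isotope = 0
    while i < n and body[i].isdigit():
        isotope = isotope * 10 + int(body[i])
        i += 1
    aromatic = False
    for tok in ("se", "as", "te"):
        if body[i:i + 2] == tok:
            sym = _AROMATIC_TOKENS[tok]
            aromatic = True
            i += 2
            break
    else:
        if i + 1 < n and body[i].isupper() and body[i + 1].islower() \
                and body[i:i + 2] not in ("H@", ):
            two = body[i:i + 2]
            try:
                atomic_number(two)
                sym = two
                i += 2
            except tables.InvalidElementError:
                sym = body[i]
                i += 1
        elif i < n and body[i].islower():
            sym = _AROMATIC_TOKENS.get(body[i])
            if sym is None:
                raise SmilesError(f"unknown aromatic symbol {body[i]!r}")
            aromatic = True
            i += 1
        elif i < n:
            sym = body[i]
            i += 1
        else:
            raise SmilesError("empty bracket atom")
    try:
        z = atomic_number(sym)
    except tables.InvalidElementError as e:
        raise SmilesError(str(e)) from None
    chir = 0
    if body[i:i + 2] == "@@":
        chir = 2
        i += 2
    elif body[i:i + 1] == "@":
        chir = 1
        i += 1
    hcount = 0
    if body[i:i + 1] == "H":
        i += 1
        hcount = 1
        if i < n and body[i].isdigit():
            hcount = int(body[i])
            i += 1
    charge = 0
    while i < n and body[i] in "+-":
        sign = 1 if body[i] == "+" else -1
        i += 1
        if i < n and body[i].isdigit():
            charge += sign * int(body[i])
            i += 1
        else:
            charge += sign
    if i != n:
        raise SmilesError(f"trailing characters in bracket atom: {body[i:]!r}")
    atom = Atom(z, formal_charge=charge, isotope_mass=isotope,
                implicit_h=hcount, explicit_h_spec=True)
    return atom, aromatic, chir, chir and hcount == 1


def _kekulize_input(mol: Molecule, aromatic_atoms: set[int],
                    arom_bond_idx: set[int]) -> None:
    if not arom_bond_idx:
        if aromatic_atoms:
            raise KekulizationError("aromatic atom outside aromatic bond system")
        return
    erased = set()
    for bi in arom_bond_idx:
        b = mol.bonds[bi]
        erased.add((min(b.a1, b.a2), max(b.a1, b.a2)))
    from .aromaticity import _pi_need   # shared needs-a-pi-bond rule
    needy = [i for i in sorted(aromatic_atoms) if _pi_need(mol, i, erased)]
    edges = sorted(erased)
    matching = match_pi_subgraph(needy, edges)
    if matching is None:
        raise KekulizationError("aromatic SMILES admits no Kekulé assignment")
    for bi in arom_bond_idx:
        b = mol.bonds[bi]
        key = (min(b.a1, b.a2), max(b.a1, b.a2))
        b.order = 2 if key in matching else 1


def _fill_implicit_h(mol: Molecule) -> None:
    for i, a in enumerate(mol.atoms):
        if a.explicit_h_spec or a.atomic_number == 1:
            continue
        s = sum(b.order for _, b in mol.covalent_neighbors(i))
        a.implicit_h = default_implicit_hydrogens(a.atomic_number,
                                                  a.formal_charge, s)


def _apply_chirality(mol, chirality, nbr_order) -> None:
    for idx, sense in chirality.items():
        refs = list(nbr_order[idx])
        if mol.atoms[idx].implicit_h == 1 and -1 not in refs:
            refs.insert(1 if refs else 0, -1)
        if len(refs) != 4:
            continue   # not a tetrahedral pattern; ignore the mark
        mol.atoms[idx].tet_stereo = (tuple(refs), sense)


def _apply_directions(mol: Molecule, directional) -> None:
    if not directional:
        return
    updir: dict[tuple[int, int], int] = {}
    for u, v, ch in directional:
        up = 1 if ch == "/" else -1      # '/' means v sits above u
        updir[(u, v)] = up
        updir[(v, u)] = -up

    def side(nbr: int, a: int) -> int | None:
        return updir.get((a, nbr))

    for b in mol.bonds:
        if b.order != 2 or b.kind is not BondKind.COVALENT or b.aromatic:
            continue
        refs = []
        for end in (b.a1, b.a2):
            pick = None
            for j, nb in mol.covalent_neighbors(end):
                if j == b.other(end) or nb.order != 1:
                    continue
                sd = side(j, end)
                if sd is not None:
                    pick = (j, sd)
                    break
            refs.append(pick)
        if refs[0] and refs[1]:
            (r1, s1), (r2, s2) = refs
            b.db_stereo = (r1, r2, "cis" if s1 == s2 else "trans")


# --------------------------------------------------------------------------
# Writer
# --------------------------------------------------------------------------


def _permutation_parity(src: tuple, dst: tuple) -> int:
    """0 for even, 1 for odd permutation mapping src order onto dst order."""
    perm = [src.index(x) for x in dst]
    parity = 0
    seen = [False] * len(perm)
    for start in range(len(perm)):
        if seen[start]:
            continue
        length = 0
        k = start
        while not seen[k]:
            seen[k] = True
            k = perm[k]
            length += 1
        parity ^= (length - 1) & 1
    return parity


def write_canonical_smiles(mol: Molecule, dearomatize: bool = True,
                           isomeric: bool = True) -> str:
    """Canonical SMILES, independent of the molecule's atom numbering.

    Nonstandard bonds are dropped first (they cannot be expressed); with
    ``dearomatize`` the Kekulé orders are written and aromatic flags
    ignored, otherwise aromatic atoms are written lowercase.
    """
    work = mol.copy()
    work.bonds = [b for b in work.bonds if b.kind is BondKind.COVALENT]
    work._rebuild_adj()
    _suppress_plain_hydrogens(work)
    if isomeric:
        _materialize_chiral_hydrogens(work)
    if not work.atoms:
        return ""
    rank = canonical_order(work)
    limit = sys.getrecursionlimit()
    needed = len(work.atoms) + 200
    if needed > limit:
        sys.setrecursionlimit(needed + 1000)
    try:
        return _Writer(work, rank, dearomatize, isomeric).run()
    finally:
        sys.setrecursionlimit(limit)


def _suppress_plain_hydrogens(mol: Molecule) -> None:
    """Fold unremarkable explicit H atoms into implicit counts.

    Hydrogens stay explicit when isotopic, charged, radical, part of H2 or
    multiply bonded, or attached to an atom with tetrahedral stereo (chiral
    centers render their hydrogen as ``[H]``).
    """
    drop: set[int] = set()
    for i, a in enumerate(mol.atoms):
        if a.atomic_number != 1 or a.isotope_mass or a.formal_charge \
                or a.radical_electrons or a.tet_stereo is not None:
            continue
        nbrs = list(mol.neighbors(i))
        if len(nbrs) != 1:
            continue
        j, b = nbrs[0]
        if b.order != 1 or mol.atoms[j].atomic_number == 1:
            continue
        if mol.atoms[j].tet_stereo is not None:
            continue
        if isinstance(b.db_stereo, tuple) or any(
                isinstance(bb.db_stereo, tuple) and i in bb.db_stereo[:2]
                for _, bb in mol.neighbors(j)):
            continue    # H serving as an E/Z reference stays explicit
        mol.atoms[j].implicit_h += 1
        drop.add(i)
    if drop:
        mol.remove_atoms(drop)


def _materialize_chiral_hydrogens(mol: Molecule) -> None:
    """Write the hydrogen of a chiral atom as an explicit [H] atom.

    Keeps the rendered string identical whether the record arrived with
    that hydrogen implicit or explicit.
    """
    for i in range(len(mol.atoms)):
        a = mol.atoms[i]
        if a.tet_stereo is None or a.implicit_h != 1:
            continue
        refs, sense = a.tet_stereo
        if -1 not in refs:
            continue
        h_idx = mol.add_atom(Atom(1))
        mol.add_bond(Bond(i, h_idx, order=1))
        a.implicit_h = 0
        a.tet_stereo = (tuple(h_idx if r == -1 else r for r in refs), sense)


class _Writer:
    def __init__(self, mol: Molecule, rank: list[int], dearomatize: bool,
                 isomeric: bool):
        self.mol = mol
        self.rank = rank
        self.dearomatize = dearomatize
        self.isomeric = isomeric
        self.parent: dict[int, int] = {}
        self.children: dict[int, list[int]] = {}
        self.closures: dict[int, list[int]] = {}   # atom -> partners (order)
        self.digit_of: dict[tuple[int, int], int] = {}
        self.visited: list[int] = []
        self.arom_atoms: set[int] = set()
        if not dearomatize:
            for b in mol.bonds:
                if b.aromatic:
                    self.arom_atoms |= {b.a1, b.a2}

    # -- traversal ---------------------------------------------------------

    def run(self) -> str:
        mol, rank = self.mol, self.rank
        n = len(mol.atoms)
        by_rank = sorted(range(n), key=lambda i: rank[i])
        seen: set[int] = set()
        pieces = []
        for root in by_rank:
            if root in seen:
                continue
            comp = self._dfs(root, seen)
            if self.isomeric:
                self.updir = _solve_directions(mol, rank)
            else:
                self.updir = {}
            pieces.append(self._emit(root))
        return ".".join(pieces)

    def _dfs(self, root: int, seen: set[int]) -> None:
        mol, rank = self.mol, self.rank
        stack = [(root, None)]
        order: set[int] = set()
        back: list[tuple[int, int]] = []
        while stack:
            u, par = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            order.add(u)
            self.visited.append(u)
            if par is not None:
                self.parent[u] = par
            self.children[u] = []
            nbrs = sorted((j for j, _ in mol.covalent_neighbors(u)),
                          key=lambda j: rank[j])
            for j in nbrs:
                if j == par:
                    continue
                if j in seen:
                    back.append((u, j))
                else:
                    pass
            # push children in reverse rank order so lowest rank pops first
            for j in reversed(nbrs):
                if j != par and j not in seen:
                    stack.append((j, u))
        # DFS with a stack may try to visit an atom twice (ring); the second
        # attempt lands in `seen` and the edge surfaces as a back edge above
        # only when the partner was already visited at scan time.  Recompute
        # back edges cleanly: tree edges are parent links, everything else is
        # a closure.
        tree = set()
        for u in order:
            p = self.parent.get(u)
            if p is not None:
                tree.add((min(u, p), max(u, p)))
                self.children[p].append(u)
        for p in self.children:
            self.children[p].sort(key=lambda j: self.rank[j])
        closures = []
        for b in mol.bonds:
            if b.a1 in order and b.a2 in order:
                key = (min(b.a1, b.a2), max(b.a1, b.a2))
                if key not in tree:
                    closures.append(key)
        # digit allocation in emission order of the opening atom
        emit_pos = {u: k for k, u in enumerate(self._emit_order(root))}
        def opener(key):
            return min(key, key=lambda x: emit_pos[x])
        closures.sort(key=lambda k: (emit_pos[opener(k)],
                                     self.rank[max(k, key=lambda x: emit_pos[x])]))
        for d, key in enumerate(closures):
            digit = d + 1
            self.digit_of[key] = digit
            a, b_ = key
            self.closures.setdefault(a, []).append(b_)
            self.closures.setdefault(b_, []).append(a)

    def _emit_order(self, root: int) -> list[int]:
        out = []
        stack = [root]
        while stack:
            u = stack.pop()
            out.append(u)
            for c in reversed(self.children.get(u, [])):
                stack.append(c)
        return out

    # -- emission ----------------------------------------------------------

    def _emit(self, root: int) -> str:
        return self._emit_atom(root)

    def _emit_atom(self, u: int) -> str:
        mol = self.mol
        parts = [self._atom_token(u)]
        emit_pos = None
        # ring closures at u, in stored order
        for v in self.closures.get(u, []):
            key = (min(u, v), max(u, v))
            digit = self.digit_of[key]
            b = mol.bond_between(u, v)
            parts.append(self._bond_token(b, u, v) + _digit_token(digit))
        kids = self.children.get(u, [])
        for k, v in enumerate(kids):
            b = mol.bond_between(u, v)
            sub = self._bond_token(b, u, v) + self._emit_atom(v)
            if k < len(kids) - 1:
                parts.append("(" + sub + ")")
            else:
                parts.append(sub)
        return "".join(parts)

    def _bond_token(self, b: Bond, u: int, v: int) -> str:
        arom = (not self.dearomatize) and b.aromatic
        if arom:
            return ""
        if b.order == 2:
            return "="
        if b.order == 3:
            return "#"
        if (not self.dearomatize) and u in self.arom_atoms and v in self.arom_atoms:
            return "-"
        if self.isomeric and b.order == 1:
            ru, rv = self.rank[u], self.rank[v]
            key = (min(ru, rv), max(ru, rv))
            t = self.updir.get(key)
            if t is not None:
                v_above_u = t if rv > ru else -t
                return "/" if v_above_u > 0 else "\\"
        return ""

    def _atom_token(self, u: int) -> str:
        mol = self.mol
        a = mol.atoms[u]
        sym = a.symbol
        aromatic = (not self.dearomatize) and u in self.arom_atoms
        token_sym = sym.lower() if aromatic else sym
        stereo = ""
        if self.isomeric and a.tet_stereo is not None:
            stereo = self._stereo_token(u)
        needs_bracket = (
            sym not in _ORGANIC_SUBSET
            or a.formal_charge != 0
            or (self.isomeric and a.isotope_mass)
            or stereo
            or a.radical_electrons
        )
        if not needs_bracket:
            # bare organic-subset atom implies the default H count
            s = sum(b.order for _, b in mol.covalent_neighbors(u))
            if a.implicit_h != default_implicit_hydrogens(
                    a.atomic_number, a.formal_charge, s):
                needs_bracket = True
        if not needs_bracket:
            return token_sym
        iso = str(a.isotope_mass) if (self.isomeric and a.isotope_mass) else ""
        h = ""
        if a.implicit_h == 1:
            h = "H"
        elif a.implicit_h > 1:
            h = f"H{a.implicit_h}"
        q = ""
        if a.formal_charge:
            sign = "+" if a.formal_charge > 0 else "-"
            mag = abs(a.formal_charge)
            q = sign if mag == 1 else f"{sign}{mag}"
        return f"[{iso}{token_sym}{stereo}{h}{q}]"

    def _written_neighbor_order(self, u: int) -> list[int]:
        order = []
        if u in self.parent:
            order.append(self.parent[u])
        if self.mol.atoms[u].implicit_h == 1:
            order.append(-1)
        order.extend(self.closures.get(u, []))
        order.extend(self.children.get(u, []))
        return order

    def _stereo_token(self, u: int) -> str:
        a = self.mol.atoms[u]
        refs, sense = a.tet_stereo
        written = self._written_neighbor_order(u)
        if sorted(written) != sorted(refs) or len(written) != 4:
            return ""
        parity = _permutation_parity(tuple(refs), tuple(written))
        if parity:
            sense = 3 - sense
        return "@" if sense == 1 else "@@"


def _digit_token(d: int) -> str:
    return str(d) if d < 10 else f"%{d:02d}"


def _solve_directions(mol: Molecule, rank: list[int]) -> dict[tuple[int, int], int]:
    """Assign up/down values to single bonds flanking stereo double bonds.

    Keys are canonical-rank pairs; t=+1 means the higher-ranked endpoint
    sits above the lower-ranked one, so the assignment is label-invariant.
    Solved as parity 2-coloring of the constraint graph; each component is
    seeded deterministically.
    """
    constraints = []   # (key1, o1, key2, o2, sigma): s1 = sigma * s2
    per_atom: dict[int, list[tuple[tuple[int, int], int]]] = {}

    def s_expr(nbr: int, at: int):
        rn, ra = rank[nbr], rank[at]
        key = (min(rn, ra), max(rn, ra))
        # s(nbr, at) = t * orient, orient +1 when nbr has the higher rank
        orient = 1 if rn > ra else -1
        return key, orient

    for b in mol.bonds:
        if b.order != 2 or not isinstance(b.db_stereo, tuple):
            continue
        r1, r2, rel = b.db_stereo
        if mol.bond_between(r1, b.a1) is None or mol.bond_between(r2, b.a2) is None:
            continue
        e1, e2 = s_expr(r1, b.a1), s_expr(r2, b.a2)
        sigma = 1 if rel == "cis" else -1
        constraints.append((e1, e2, sigma))
        per_atom.setdefault(b.a1, []).append(e1)
        per_atom.setdefault(b.a2, []).append(e2)
    # neighbors annotated on the same double-bond atom sit on opposite sides
    for at, exprs in per_atom.items():
        uniq = {k: o for k, o in exprs}
        items = sorted(uniq.items())
        for x in range(len(items) - 1):
            (k1, o1), (k2, o2) = items[x], items[x + 1]
            if k1 != k2:
                constraints.append(((k1, o1), (k2, o2), -1))

    adj: dict[tuple[int, int], list] = {}
    for (k1, o1), (k2, o2), sigma in constraints:
        # t1 * o1 = sigma * t2 * o2  ->  t1 = (sigma*o1*o2) * t2
        rel = sigma * o1 * o2
        adj.setdefault(k1, []).append((k2, rel))
        adj.setdefault(k2, []).append((k1, rel))
    t: dict[tuple[int, int], int] = {}
    for seed in sorted(adj):
        if seed in t:
            continue
        t[seed] = 1
        queue = [seed]
        while queue:
            k = queue.pop()
            for k2, rel in adj[k]:
                want = rel * t[k]
                if k2 in t:
                    continue   # conflicts tolerated: first assignment wins
                t[k2] = want
                queue.append(k2)
    return t
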
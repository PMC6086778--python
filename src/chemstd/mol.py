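"""The molecular graph model every standardization step operates on.

A :class:`Molecule` is an attributed graph: atoms carry element, formal
charge, isotope, implicit-hydrogen count, radical electrons, optional
coordinates and tetrahedral stereo; bonds carry an integer order, a bond
kind (covalent or one of the zero-order kinds: ionic, complex, dative), an
aromaticity flag, wedge/crossed depiction flags and optional double-bond
stereo.

Valence is the bond-order sum over *covalent* bonds plus implicit
hydrogens; ionic, complex and dative bonds contribute nothing.

Atom indices are 0-based internally; file formats translate at the I/O
boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import networkx as nx

from . import tables

__all__ = [
    "BondKind", "Wedge", "Atom", "Bond", "Molecule",
    "atom_valence", "covalent_components", "symmetry_classes",
    "canonical_order", "smallest_ring_size",
]


class BondKind(enum.Enum):
    COVALENT = "covalent"
    IONIC = "ionic"
    COMPLEX = "complex"
    DATIVE = "dative"


class Wedge(enum.Enum):
    NONE = 0
    UP = 1
    DOWN = 6


# Tetrahedral stereo: (ordered neighbor refs, sense).  Refs are atom indices,
# -1 standing for the implicit hydrogen.  sense=1 means that viewed with the
# first ref pointing toward the viewer, the remaining three run
# counterclockwise (the '@' sense); sense=2 is clockwise ('@@').
TetStereo = tuple[tuple[int, int, int, int], int]

# Double-bond stereo: (ref neighbor of a1, ref neighbor of a2, relation)
# where relation is "cis" (same side) or "trans" (opposite sides).
# The string "undefined" marks an explicitly undefined (crossed) bond.
DBStereo = "tuple[int, int, str] | str"


@dataclass
class Atom:
    atomic_number: int
    formal_charge: int = 0
    isotope_mass: int = 0          # 0 = natural abundance / unspecified
    implicit_h: int = 0
    radical_electrons: int = 0
    coords: tuple[float, ...] | None = None
    tet_stereo: TetStereo | None = None
    explicit_h_spec: bool = False  # input pinned the hydrogen count

    @property
    def symbol(self) -> str:
        return tables.symbol(self.atomic_number)

    def copy(self) -> "Atom":
        return replace(self)


@dataclass
class Bond:
    a1: int
    a2: int
    order: int = 1                 # meaningful for covalent bonds only
    kind: BondKind = BondKind.COVALENT
    aromatic: bool = False
    wedge: Wedge = Wedge.NONE
    crossed: bool = False          # drawn as crossed double bond (undefined E/Z)
    db_stereo: object | None = None  # DBStereo

    def other(self, idx: int) -> int:
        return self.a2 if idx == self.a1 else self.a1

    def copy(self) -> "Bond":
        return replace(self)


class Molecule:
    """Ordered atom list + bond list with O(1) incidence lookup."""

    def __init__(self):
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self.dimensionality: int = 0   # 0 = none, 2, or 3
        self.properties: dict[str, str] = {}
        self._adj: list[dict[int, int]] = []   # atom -> {neighbor: bond index}

    # -- construction ------------------------------------------------------

    def add_atom(self, atom: Atom) -> int:
        self.atoms.append(atom)
        self._adj.append({})
        return len(self.atoms) - 1

    def add_bond(self, bond: Bond) -> int:
        if bond.a1 == bond.a2:
            raise ValueError("self-bond")
        if bond.a2 in self._adj[bond.a1]:
            raise ValueError(f"duplicate bond {bond.a1}-{bond.a2}")
        self.bonds.append(bond)
        bi = len(self.bonds) - 1
        self._adj[bond.a1][bond.a2] = bi
        self._adj[bond.a2][bond.a1] = bi
        return bi

    def copy(self) -> "Molecule":
        m = Molecule()
        m.atoms = [a.copy() for a in self.atoms]
        m.bonds = [b.copy() for b in self.bonds]
        m.dimensionality = self.dimensionality
        m.properties = dict(self.properties)
        m._adj = [dict(d) for d in self._adj]
        return m

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def bond_between(self, i: int, j: int) -> Bond | None:
        bi = self._adj[i].get(j)
        return None if bi is None else self.bonds[bi]

    def neighbors(self, i: int, kinds: tuple[BondKind, ...] | None = None):
        """(neighbor index, bond) pairs, optionally filtered by bond kind."""
        for j, bi in self._adj[i].items():
            b = self.bonds[bi]
            if kinds is None or b.kind in kinds:
                yield j, b

    def covalent_neighbors(self, i: int):
        return self.neighbors(i, (BondKind.COVALENT,))

    def degree(self, i: int) -> int:
        """Explicit covalent degree (implicit hydrogens not counted)."""
        return sum(1 for _ in self.covalent_neighbors(i))

    def total_h(self, i: int) -> int:
        """Implicit plus explicit attached hydrogens."""
        n = self.atoms[i].implicit_h
        for j, b in self.covalent_neighbors(i):
            if self.atoms[j].atomic_number == 1:
                n += 1
        return n

    def remove_bond_between(self, i: int, j: int) -> None:
        bi = self._adj[i].pop(j)
        self._adj[j].pop(i)
        self.bonds.pop(bi)
        self._reindex()

    def remove_atoms(self, drop: set[int]) -> dict[int, int]:
        """Delete atoms (and incident bonds); returns old->new index map."""
        keep = [i for i in range(len(self.atoms)) if i not in drop]
        remap = {old: new for new, old in enumerate(keep)}
        self.atoms = [self.atoms[i] for i in keep]
        new_bonds = []
        for b in self.bonds:
            if b.a1 in drop or b.a2 in drop:
                continue
            nb = b.copy()
            nb.a1, nb.a2 = remap[b.a1], remap[b.a2]
            nb = _remap_bond_stereo(nb, remap)
            new_bonds.append(nb)
        self.bonds = new_bonds
        for a in self.atoms:
            if a.tet_stereo is not None:
                refs, sense = a.tet_stereo
                if any(r in drop for r in refs if r >= 0):
                    a.tet_stereo = None
                else:
                    a.tet_stereo = (tuple(remap[r] if r >= 0 else -1 for r in refs),
                                    sense)
        self._rebuild_adj()
        return remap

    def _rebuild_adj(self) -> None:
        self._adj = [{} for _ in self.atoms]
        for bi, b in enumerate(self.bonds):
            self._adj[b.a1][b.a2] = bi
            self._adj[b.a2][b.a1] = bi

    def _reindex(self) -> None:
        self._rebuild_adj()

    def permuted(self, perm: list[int]) -> "Molecule":
        """Relabeled copy; ``perm[old] = new`` position of each atom."""
        m = Molecule()
        inv = [0] * len(perm)
        for old, new in enumerate(perm):
            inv[new] = old
        for new in range(len(perm)):
            m.add_atom(self.atoms[inv[new]].copy())
        for i, a in enumerate(m.atoms):
            if a.tet_stereo is not None:
                refs, sense = a.tet_stereo
                a.tet_stereo = (tuple(perm[r] if r >= 0 else -1 for r in refs), sense)
        for b in self.bonds:
            nb = b.copy()
            nb.a1, nb.a2 = perm[b.a1], perm[b.a2]
            nb = _remap_bond_stereo(nb, {i: p for i, p in enumerate(perm)})
            m.add_bond(nb)
        m.dimensionality = self.dimensionality
        m.properties = dict(self.properties)
        return m


def _remap_bond_stereo(b: Bond, remap: dict[int, int]) -> Bond:
    if isinstance(b.db_stereo, tuple):
        r1, r2, rel = b.db_stereo
        if r1 in remap and r2 in remap:
            b.db_stereo = (remap[r1], remap[r2], rel)
        else:
            b.db_stereo = None
    return b


# --------------------------------------------------------------------------
# Valence accounting and components
# --------------------------------------------------------------------------


def atom_valence(mol: Molecule, i: int) -> int:
    """Bond-order sum over covalent bonds plus implicit hydrogens.

    Ionic, complex and dative bonds are zero-order: they never contribute.
    """
    v = mol.atoms[i].implicit_h
    for _, b in mol.covalent_neighbors(i):
        v += b.order
    return v


def sigma_pi_counts(mol: Molecule, i: int) -> tuple[int, int]:
    """(sigma, pi) bond counts over explicit covalent bonds.

    Every covalent neighbor contributes one sigma bond; a double bond adds
    one pi, a triple bond two.  Implicit hydrogens are not included.
    """
    ns = npi = 0
    for _, b in mol.covalent_neighbors(i):
        ns += 1
        npi += b.order - 1
    return ns, npi


def covalent_components(mol: Molecule) -> list[set[int]]:
    """Partition of atom indices by covalent connectivity.

    Nonstandard (zero-order) bonds do not join components: the ions of a
    salt and the ligands of a complex are separate components.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((b.a1, b.a2) for b in mol.bonds if b.kind is BondKind.COVALENT)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=min)


# --------------------------------------------------------------------------
# Ring perception
# --------------------------------------------------------------------------


def _covalent_graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    for b in mol.bonds:
        if b.kind is BondKind.COVALENT:
            g.add_edge(b.a1, b.a2)
    return g


def sssr(mol: Molecule) -> list[list[int]]:
    """A smallest-set-of-smallest-rings-style cycle basis (covalent graph)."""
    return [list(c) for c in nx.minimum_cycle_basis(_covalent_graph(mol))]


def smallest_ring_size(mol: Molecule, i: int, j: int | None = None) -> int:
    """Size of the smallest ring containing atom i (and bond i-j if given).

    Returns 0 when not in any ring.
    """
    g = _covalent_graph(mol)
    if j is not None:
        if not g.has_edge(i, j):
            return 0
        g.remove_edge(i, j)
        try:
            return nx.shortest_path_length(g, i, j) + 1
        except nx.NetworkXNoPath:
            return 0
    best = 0
    for nb in list(g.neighbors(i)):
        n = smallest_ring_size(mol, i, nb)
        if n and (best == 0 or n < best):
            best = n
    return best


def ring_atoms(mol: Molecule) -> set[int]:
    g = _covalent_graph(mol)
    out: set[int] = set()
    for comp in nx.biconnected_components(g):
        if len(comp) > 2:
            out |= comp
    return out


# --------------------------------------------------------------------------
# Symmetry classes and canonical order
# --------------------------------------------------------------------------


def _initial_invariants(mol: Molecule) -> list[tuple]:
    in_ring = ring_atoms(mol)
    inv = []
    for i, a in enumerate(mol.atoms):
        inv.append((
            a.atomic_number,
            a.formal_charge,
            mol.degree(i),
            mol.total_h(i),
            a.isotope_mass,
            1 if i in in_ring else 0,
        ))
    return inv


def _refine(mol: Molecule, classes: list[int]) -> list[int]:
    """Iterative neighborhood refinement to a fixed point.

    Classes only ever split (monotone); the fixed point is reached within
    |atoms| iterations.
    """
    n = len(mol.atoms)
    for _ in range(n + 1):
        sig = []
        for i in range(n):
            nbr = sorted((b.order if b.kind is BondKind.COVALENT else 0,
                          classes[j])
                         for j, b in mol.neighbors(i))
            sig.append((classes[i], tuple(nbr)))
        order = sorted(range(n), key=lambda i: sig[i])
        new = [0] * n
        c = 0
        for k, i in enumerate(order):
            if k and sig[i] != sig[order[k - 1]]:
                c += 1
            new[i] = c
        if new == classes:
            break
        classes = new
    return classes


def symmetry_classes(mol: Molecule) -> list[int]:
    """Per-atom symmetry class labels by Morgan-style relaxation.

    Explicit hydrogen atoms are pinned to class 0 (lowest priority); other
    classes are numbered from 1 upward by the canonical order of their
    smallest invariant.  Atoms with equal labels are equivalent under the
    refinement invariants (element, charge, degree, attached H, isotope,
    ring membership, then iterated neighborhoods).
    """
    n = len(mol.atoms)
    inv = _initial_invariants(mol)
    ordering = sorted(range(n), key=lambda i: inv[i])
    classes = [0] * n
    c = 0
    for k, i in enumerate(ordering):
        if k and inv[i] != inv[ordering[k - 1]]:
            c += 1
        classes[i] = c
    classes = _refine(mol, classes)
    # renumber: explicit hydrogens -> 0, others 1.. in class order
    is_h = [a.atomic_number == 1 for a in mol.atoms]
    distinct = sorted({classes[i] for i in range(n) if not is_h[i]})
    remap = {cl: k + 1 for k, cl in enumerate(distinct)}
    return [0 if is_h[i] else remap[classes[i]] for i in range(n)]


def _partition_from_classes(classes: list[int]) -> list[list[int]]:
    cells: dict[int, list[int]] = {}
    for i, c in enumerate(classes):
        cells.setdefault(c, []).append(i)
    return [cells[c] for c in sorted(cells)]


def _certificate(mol: Molecule, rank: dict[int, int]) -> tuple:
    """Complete label-independent code of the molecule under an atom ranking."""
    n = len(mol.atoms)
    inv_rank = [0] * n
    for i, r in rank.items():
        inv_rank[r] = i
    atoms = []
    for r in range(n):
        a = mol.atoms[inv_rank[r]]
        atoms.append((a.atomic_number, a.formal_charge, a.isotope_mass,
                      a.implicit_h, a.radical_electrons))
    edges = sorted(
        (min(rank[b.a1], rank[b.a2]), max(rank[b.a1], rank[b.a2]),
         b.order if b.kind is BondKind.COVALENT else 0, b.kind.value)
        for b in mol.bonds)
    return (tuple(atoms), tuple(edges))


def _canon_search(mol: Molecule, classes: list[int], best: list) -> None:
    classes = _refine(mol, classes)
    cells = _partition_from_classes(classes)
    target = next((cell for cell in cells if len(cell) > 1), None)
    if target is None:
        rank = {}
        for r, cell in enumerate(cells):
            rank[cell[0]] = r
        cert = _certificate(mol, rank)
        if best[0] is None or cert < best[0]:
            best[0] = cert
            best[1] = rank
        return
    nclass = max(classes) + 1
    for i in target:
        child = list(classes)
        child[i] = nclass
        _canon_search(mol, child, best)


def canonical_order(mol: Molecule) -> list[int]:
    """Canonical rank of each atom (``rank[i]`` = canonical position).

    Deterministic and invariant under input atom permutation: refinement of
    the initial invariants, then branch on tied cells choosing the
    minimal complete adjacency certificate.
    """
    n = len(mol.atoms)
    if n == 0:
        return []
    inv = _initial_invariants(mol)
    ordering = sorted(range(n), key=lambda i: inv[i])
    classes = [0] * n
    c = 0
    for k, i in enumerate(ordering):
        if k and inv[i] != inv[ordering[k - 1]]:
            c += 1
        classes[i] = c
    best: list = [None, None]
    _canon_search(mol, classes, best)
    rank = best[1]
    return [rank[i] for i in range(n)]


def canonicalized(mol: Molecule) -> Molecule:
    """Copy of the molecule with atoms renumbered into canonical order."""
    return mol.permuted(canonical_order(mol))
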
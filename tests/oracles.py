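"""Independent brute-force tautomer oracle used by the test suite.

Molecule-level move closure (copies + canonical-key dedup) plus a full
sort by the scoring ladder, with the tie-goes-to-original and arbitration
rules; written separately from the production walk so the two can check
each other.
"""

from chemstd.mol import BondKind
from chemstd.smiles import write_canonical_smiles
from chemstd.tautomer import energetic_class, immobilized_charges, prefer, score_state



def _oracle_moves(mol):
    """All single proton/charge shifts, applied on molecule copies."""
    out = []
    n = len(mol.atoms)

    def bond(i, j):
        return mol.bond_between(i, j)

    def donors():
        for x in range(n):
            a = mol.atoms[x]
            h = a.implicit_h
            if h < 1:
                continue
            if a.atomic_number == 6 and h != 1:
                continue
            if a.atomic_number not in (6, 7, 8, 15, 16):
                continue
            yield x

    for x in donors():
        for y, bxy in mol.covalent_neighbors(x):
            if bxy.order != 1:
                continue
            for z, byz in mol.covalent_neighbors(y):
                if z == x or byz.order != 2:
                    continue
                if mol.atoms[z].atomic_number in (7, 8, 15, 16):
                    m = mol.copy()
                    m.bond_between(x, y).order = 2
                    m.bond_between(y, z).order = 1
                    m.atoms[x].implicit_h -= 1
                    m.atoms[z].implicit_h += 1
                    out.append(m)
                for w, bzw in mol.covalent_neighbors(z):
                    if w in (x, y) or bzw.order != 1:
                        continue
                    for v, bwv in mol.covalent_neighbors(w):
                        if v in (x, y, z) or bwv.order != 2:
                            continue
                        if mol.atoms[v].atomic_number not in (7, 8, 15, 16):
                            continue
                        m = mol.copy()
                        m.bond_between(x, y).order = 2
                        m.bond_between(y, z).order = 1
                        m.bond_between(z, w).order = 2
                        m.bond_between(w, v).order = 1
                        m.atoms[x].implicit_h -= 1
                        m.atoms[v].implicit_h += 1
                        out.append(m)
    frozen = {i for i, _ in immobilized_charges(mol)}
    for x in range(n):
        q = mol.atoms[x].formal_charge
        if q not in (-1, 1) or x in frozen:
            continue
        if mol.atoms[x].atomic_number not in (6, 7, 8, 15, 16):
            continue
        for y, bxy in mol.covalent_neighbors(x):
            if bxy.order != 1:
                continue
            for z, byz in mol.covalent_neighbors(y):
                if z == x or byz.order != 2 or z in frozen:
                    continue
                if mol.atoms[z].formal_charge != 0:
                    continue
                if mol.atoms[z].atomic_number not in (6, 7, 8, 15, 16):
                    continue
                m = mol.copy()
                m.bond_between(x, y).order = 2
                m.bond_between(y, z).order = 1
                m.atoms[x].formal_charge = 0
                m.atoms[z].formal_charge = q
                out.append(m)
    return out


def _oracle_best(mol):
    """Closure over moves, then full sort by the scoring ladder with the
    tie-goes-to-original and arbitration rules applied."""
    start_key = write_canonical_smiles(mol)
    base_class = energetic_class([a.atomic_number for a in mol.atoms],
                                 [a.formal_charge for a in mol.atoms])
    seen = {start_key: mol}
    frontier = [mol]
    while frontier:
        nxt = []
        for m in frontier:
            for cand in _oracle_moves(m):
                if energetic_class([a.atomic_number for a in cand.atoms],
                                   [a.formal_charge for a in cand.atoms]) \
                        < base_class:
                    continue
                k = write_canonical_smiles(cand)
                if k not in seen:
                    seen[k] = cand
                    nxt.append(cand)
        frontier = nxt
        assert len(seen) < 5000
    orig_score = score_state(mol)
    best = None
    for k, cand in seen.items():
        if k == start_key:
            continue
        sc = score_state(cand)
        if best is None or prefer(sc, best[1]):
            best = (cand, sc)
    if best is None:
        return start_key
    if prefer(best[1], orig_score):
        return write_canonical_smiles(best[0])

    def arb(m):
        cc = nn = 0
        for b in m.bonds:
            if b.order == 2 and b.kind is BondKind.COVALENT:
                z1, z2 = m.atoms[b.a1].atomic_number, m.atoms[b.a2].atomic_number
                if z1 == z2 == 6:
                    cc += 1
                elif z1 == z2 == 7:
                    nn += 1
        return cc - 2 * nn

    if arb(best[0]) < arb(mol):
        return write_canonical_smiles(best[0])
    return start_key
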
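"""SDF / MOL (MDL V2000) reading and writing.

Both isotope dialects are understood: the atom-block mass *delta* relative
to the most common isotope, and the absolute ``M  ISO`` property line; on
conflict ``M  ISO`` wins.  Wedge flags (1 up, 6 down) and the crossed
double bond (bond stereo 3) are preserved.  Nonstandard (ionic, complex,
dative) bonds are not part of the V2000 bond block: they travel in the
``NONSTANDARD_BONDS`` data field, one ``<a1> <a2> <kind>`` line per bond
with 1-based atom indices.

Reading is strict on the counts line and bond indices, lenient on trailing
whitespace; a malformed record yields a record-level error and the stream
continues with the next ``$$$$`` delimited record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mol import Atom, Bond, BondKind, Molecule, Wedge
from .tables import SYMBOLS, atomic_number

__all__ = ["SdfRecord", "SdfParseError", "CapacityError",
           "read_sdf", "write_sdf", "parse_molblock", "write_molblock"]

NONSTANDARD_BOND_FIELD = "NONSTANDARD_BONDS"

V2000_LIMIT = 999

# Mass number of the most common isotope (atom-block deltas are relative to
# it).  Curated for the frequently deposited elements; anything else falls
# back to the midpoint of the isotope window.
_MOST_COMMON_A = {
    "H": 1, "He": 4, "Li": 7, "Be": 9, "B": 11, "C": 12, "N": 14, "O": 16,
    "F": 19, "Ne": 20, "Na": 23, "Mg": 24, "Al": 27, "Si": 28, "P": 31,
    "S": 32, "Cl": 35, "Ar": 40, "K": 39, "Ca": 40, "Sc": 45, "Ti": 48,
    "V": 51, "Cr": 52, "Mn": 55, "Fe": 56, "Co": 59, "Ni": 58, "Cu": 63,
    "Zn": 64, "Ga": 69, "Ge": 74, "As": 75, "Se": 80, "Br": 79, "Kr": 84,
    "Rb": 85, "Sr": 88, "Y": 89, "Zr": 90, "Nb": 93, "Mo": 98, "Tc": 98,
    "Ru": 102, "Rh": 103, "Pd": 106, "Ag": 107, "Cd": 114, "In": 115,
    "Sn": 120, "Sb": 121, "Te": 130, "I": 127, "Xe": 132, "Cs": 133,
    "Ba": 138, "La": 139, "Ce": 140, "W": 184, "Pt": 195, "Au": 197,
    "Hg": 202, "Tl": 205, "Pb": 208, "Bi": 209, "Th": 232, "U": 238,
}

_CHARGE_CODE = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
_CODE_CHARGE = {v: k for k, v in _CHARGE_CODE.items()}


class SdfParseError(ValueError):
    pass


class CapacityError(ValueError):
    """Molecule exceeds the V2000 atom/bond limit of 999."""


@dataclass
class SdfRecord:
    molecule: Molecule
    title: str = ""
    data_fields: dict[str, str] = field(default_factory=dict)
    error: str | None = None       # record-level parse error, molecule empty


def most_common_mass(z: int) -> int:
    sym = SYMBOLS[z]
    if sym in _MOST_COMMON_A:
        return _MOST_COMMON_A[sym]
    from .tables import _isotope_window
    lo, hi = _isotope_window(z)
    return (lo + hi) // 2


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------


def parse_molblock(lines: list[str]) -> tuple[Molecule, str]:
    """Parse the molfile part (header + ctab, up to M END)."""
    if len(lines) < 4:
        raise SdfParseError("truncated molfile header")
    title = lines[0].rstrip("\n")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise SdfParseError(f"malformed counts line: {counts!r}") from None
    if "V2000" not in counts and counts[33:39].strip() not in ("", "V2000"):
        raise SdfParseError("only V2000 connection tables are supported")
    mol = Molecule()
    deltas: list[int] = []
    radical_codes: list[int] = []
    parities: list[int] = []
    idx = 4
    any_coord = False
    for k in range(n_atoms):
        if idx >= len(lines):
            raise SdfParseError("truncated atom block")
        ln = lines[idx]
        idx += 1
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            sym = ln[31:34].strip()
            delta = int(ln[34:36]) if ln[34:36].strip() else 0
            ccode = int(ln[36:39]) if ln[36:39].strip() else 0
            par = int(ln[39:42]) if ln[39:42].strip() else 0
            vflag = int(ln[48:51]) if len(ln) > 48 and ln[48:51].strip() else 0
        except ValueError as e:
            raise SdfParseError(f"malformed atom line {k + 1}: {e}") from None
        try:
            zn = atomic_number(sym)
        except Exception:
            raise SdfParseError(f"unknown element {sym!r} in atom line {k + 1}")
        a = Atom(zn)
        if (x, y, z) != (0.0, 0.0, 0.0):
            any_coord = True
        a.coords = (x, y, z)
        a.formal_charge = _CHARGE_CODE.get(ccode, 0)
        if ccode == 4:
            radical_codes.append(k)
        if vflag:
            a.explicit_h_spec = True
            a._v2000_valence = vflag      # resolved after bonds are read
        deltas.append(delta)
        parities.append(par)
        mol.add_atom(a)
    for k in range(n_bonds):
        if idx >= len(lines):
            raise SdfParseError("truncated bond block")
        ln = lines[idx]
        idx += 1
        try:
            a1 = int(ln[0:3]) - 1
            a2 = int(ln[3:6]) - 1
            order = int(ln[6:9])
            stereo = int(ln[9:12]) if ln[9:12].strip() else 0
        except ValueError as e:
            raise SdfParseError(f"malformed bond line {k + 1}: {e}") from None
        if not (0 <= a1 < n_atoms and 0 <= a2 < n_atoms):
            raise SdfParseError(f"bond index out of range in line {k + 1}")
        b = Bond(a1, a2)
        if order == 4:
            b.order = 1
            b.aromatic = True    # pending re-perception
        elif order in (1, 2, 3):
            b.order = order
        else:
            b.order = 1
            b.aromatic = True
        if stereo == 1:
            b.wedge = Wedge.UP
        elif stereo == 6:
            b.wedge = Wedge.DOWN
        elif stereo == 3 and b.order == 2:
            b.crossed = True
            b.db_stereo = "undefined"
        mol.add_bond(b)
    # properties block
    saw_chg = saw_iso = False
    iso_abs: dict[int, int] = {}
    chg: dict[int, int] = {}
    rad: dict[int, int] = {}
    while idx < len(lines):
        ln = lines[idx].rstrip("\n")
        idx += 1
        if ln.startswith("M  END") or ln.startswith("M END"):
            break
        if ln.startswith("M  CHG"):
            saw_chg = True
            _parse_m_pairs(ln, chg)
        elif ln.startswith("M  ISO"):
            saw_iso = True
            _parse_m_pairs(ln, iso_abs)
        elif ln.startswith("M  RAD"):
            _parse_m_pairs(ln, rad)
        elif ln.startswith(("A  ", "G  ", "V  ")) or ln.startswith("M  "):
            raise SdfParseError(f"unsupported property line: {ln!r}")
    if saw_chg:
        for a in mol.atoms:
            a.formal_charge = 0
        for i, q in chg.items():
            mol.atoms[i].formal_charge = q
    for i in radical_codes:
        mol.atoms[i].radical_electrons = 2   # atom-block code 4: doublet
    for i, r in rad.items():
        mol.atoms[i].radical_electrons = {1: 2, 2: 1, 3: 2}.get(r, 0)
    for i, delta in enumerate(deltas):
        if delta:
            mol.atoms[i].isotope_mass = most_common_mass(
                mol.atoms[i].atomic_number) + delta
    if saw_iso:
        for i, aabs in iso_abs.items():
            mol.atoms[i].isotope_mass = aabs   # absolute value wins
    mol.dimensionality = 0
    if any_coord:
        mol.dimensionality = 3 if any(
            a.coords and abs(a.coords[2]) > 1e-9 for a in mol.atoms) else 2
    _resolve_valence_flags(mol)
    _fill_implicit(mol)
    _parities_to_stereo(mol, parities)
    return mol, title


def _parse_m_pairs(ln: str, out: dict[int, int]) -> None:
    parts = ln.split()
    try:
        cnt = int(parts[2])
        vals = parts[3:3 + 2 * cnt]
        for k in range(cnt):
            out[int(vals[2 * k]) - 1] = int(vals[2 * k + 1])
    except (ValueError, IndexError):
        raise SdfParseError(f"malformed property line: {ln!r}") from None


def _resolve_valence_flags(mol: Molecule) -> None:
    for i, a in enumerate(mol.atoms):
        v = getattr(a, "_v2000_valence", None)
        if v is None:
            continue
        del a.__dict__["_v2000_valence"]
        total = 0 if v == 15 else v
        s = sum(b.order for _, b in mol.covalent_neighbors(i))
        a.implicit_h = max(0, total - s)


def _fill_implicit(mol: Molecule) -> None:
    from .tables import default_implicit_hydrogens
    for i, a in enumerate(mol.atoms):
        if a.explicit_h_spec or a.atomic_number == 1:
            continue
        s = sum(b.order for _, b in mol.covalent_neighbors(i))
        h = default_implicit_hydrogens(a.atomic_number, a.formal_charge, s)
        a.implicit_h = max(0, h - a.radical_electrons)


def _parities_to_stereo(mol: Molecule, parities: list[int]) -> None:
    """Atom-block parity -> internal tetrahedral stereo.

    MDL parity orders the neighbors by atom number (implicit H last); code
    1 means the last three run clockwise viewed from the first.
    """
    for i, p in enumerate(parities):
        if p not in (1, 2):
            continue
        refs = sorted(j for j, _ in mol.covalent_neighbors(i))
        if mol.atoms[i].implicit_h == 1:
            refs.append(-1)
        if len(refs) != 4:
            continue
        sense = 2 if p == 1 else 1
        mol.atoms[i].tet_stereo = (tuple(refs), sense)


def read_sdf(stream):
    """Iterate :class:`SdfRecord` from an SDF stream.

    A malformed record is reported (``record.error``) and parsing resumes
    at the next ``$$$$`` line.
    """
    lines: list[str] = []
    for raw in stream:
        line = raw.rstrip("\n")
        if line.strip() == "$$$$":
            if any(l.strip() for l in lines):
                yield _parse_record(lines)
            lines = []
        else:
            lines.append(line)
    if any(l.strip() for l in lines):
        yield _parse_record(lines)


def _parse_record(lines: list[str]) -> SdfRecord:
    # split molblock from data fields at M END
    end = None
    for k, ln in enumerate(lines):
        if ln.startswith("M  END") or ln.startswith("M END"):
            end = k
            break
    try:
        mol, title = parse_molblock(lines[:end + 1] if end is not None else lines)
    except SdfParseError as e:
        return SdfRecord(Molecule(), error=str(e))
    fields: dict[str, str] = {}
    k = (end + 1) if end is not None else len(lines)
    name = None
    buf: list[str] = []
    while k < len(lines):
        ln = lines[k]
        if ln.startswith(">"):
            if name is not None:
                fields[name] = "\n".join(buf).rstrip("\n")
            l, r = ln.find("<"), ln.rfind(">")
            name = ln[l + 1:r] if 0 <= l < r else ln[1:].strip()
            buf = []
        elif name is not None:
            if ln.strip() == "":
                fields[name] = "\n".join(buf)
                name = None
                buf = []
            else:
                buf.append(ln)
        k += 1
    if name is not None:
        fields[name] = "\n".join(buf)
    rec = SdfRecord(mol, title=title, data_fields=fields)
    _apply_nonstandard_bond_field(rec)
    return rec


def _apply_nonstandard_bond_field(rec: SdfRecord) -> None:
    text = rec.data_fields.get(NONSTANDARD_BOND_FIELD)
    if not text:
        return
    for ln in text.splitlines():
        parts = ln.split()
        if len(parts) != 3:
            continue
        a1, a2, kind = int(parts[0]) - 1, int(parts[1]) - 1, parts[2]
        try:
            bk = BondKind(kind)
        except ValueError:
            continue
        if rec.molecule.bond_between(a1, a2) is None:
            rec.molecule.add_bond(Bond(a1, a2, order=1, kind=bk))
        else:
            b = rec.molecule.bond_between(a1, a2)
            b.kind = bk


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------


def write_molblock(mol: Molecule, title: str = "") -> str:
    cov = [b for b in mol.bonds if b.kind is BondKind.COVALENT]
    if len(mol.atoms) > V2000_LIMIT or len(cov) > V2000_LIMIT:
        raise CapacityError(
            f"{len(mol.atoms)} atoms / {len(cov)} bonds exceed the "
            f"V2000 limit of {V2000_LIMIT}")
    out = [title[:80], "  chemstd", "", ""]
    out[3] = f"{len(mol.atoms):3d}{len(cov):3d}  0  0  0  0  0  0  0  0999 V2000"
    parities = _stereo_to_parities(mol)
    for i, a in enumerate(mol.atoms):
        x, y, z = (a.coords + (0.0,) * 3)[:3] if a.coords else (0.0, 0.0, 0.0)
        out.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.symbol:<3s} 0  0"
                   f"{parities[i]:3d}  0  0  0  0  0  0  0  0  0")
    for b in cov:
        stereo = 0
        if b.wedge is Wedge.UP:
            stereo = 1
        elif b.wedge is Wedge.DOWN:
            stereo = 6
        elif b.crossed or b.db_stereo == "undefined":
            stereo = 3 if b.order == 2 else 0
        out.append(f"{b.a1 + 1:3d}{b.a2 + 1:3d}{b.order:3d}{stereo:3d}  0  0  0")
    charged = [(i + 1, a.formal_charge) for i, a in enumerate(mol.atoms)
               if a.formal_charge]
    for chunk in _chunks(charged, 8):
        out.append("M  CHG" + f"{len(chunk):3d}" +
                   "".join(f"{i:4d}{q:4d}" for i, q in chunk))
    isotopic = [(i + 1, a.isotope_mass) for i, a in enumerate(mol.atoms)
                if a.isotope_mass]
    for chunk in _chunks(isotopic, 8):
        out.append("M  ISO" + f"{len(chunk):3d}" +
                   "".join(f"{i:4d}{m:4d}" for i, m in chunk))
    radicals = [(i + 1, {1: 2, 2: 1}.get(a.radical_electrons, 3))
                for i, a in enumerate(mol.atoms) if a.radical_electrons]
    for chunk in _chunks(radicals, 8):
        out.append("M  RAD" + f"{len(chunk):3d}" +
                   "".join(f"{i:4d}{r:4d}" for i, r in chunk))
    out.append("M  END")
    return "\n".join(out) + "\n"


def _stereo_to_parities(mol: Molecule) -> list[int]:
    from .smiles import _permutation_parity
    out = [0] * len(mol.atoms)
    for i, a in enumerate(mol.atoms):
        if a.tet_stereo is None:
            continue
        refs, sense = a.tet_stereo
        target = sorted(r for r in refs if r >= 0)
        if -1 in refs:
            target.append(-1)
        if sorted(target) != sorted(refs) or len(refs) != 4:
            continue
        parity = _permutation_parity(tuple(refs), tuple(target))
        eff = sense if parity == 0 else 3 - sense
        out[i] = 1 if eff == 2 else 2
    return out


def write_sdf(records, stream, nonstandard_bond_field: bool = True) -> None:
    """Write records (SdfRecord or Molecule) as an SDF stream.

    Nonstandard bonds are omitted from the bond block; with the default
    ``nonstandard_bond_field`` they are emitted in the
    ``NONSTANDARD_BONDS`` data field.
    """
    for rec in records:
        if isinstance(rec, Molecule):
            rec = SdfRecord(rec)
        mol = rec.molecule
        stream.write(write_molblock(mol, rec.title))
        fields = dict(rec.data_fields)
        fields.pop(NONSTANDARD_BOND_FIELD, None)
        ns = [b for b in mol.bonds if b.kind is not BondKind.COVALENT]
        if ns and nonstandard_bond_field:
            fields[NONSTANDARD_BOND_FIELD] = "\n".join(
                f"{b.a1 + 1} {b.a2 + 1} {b.kind.value}" for b in ns)
        for name, value in fields.items():
            stream.write(f"> <{name}>\n{value}\n\n")
        stream.write("$$$$\n")


def _chunks(seq, n):
    for k in range(0, len(seq), n):
        yield seq[k:k + n]
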
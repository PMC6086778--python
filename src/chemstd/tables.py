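"""Static chemical knowledge consulted by the standardization pipeline.

Four knowledgebases live here:

* element classification (organic / metal / transition metal / semiconductor /
  unclassified) used by the hydrogen, functional-group and bonding rules;
* the isotope validity table (nuclides with half-life above 1 ms);
* the valence knowledgebase: allowed (element, charge, sigma, pi) atom
  configurations with the maximum permitted implicit hydrogen count;
* the default (MDL-style) valence model used to fill implicit hydrogens.

All lookups are pure functions of their arguments.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "ElementClass",
    "ValenceRule",
    "ValenceTable",
    "MAX_Z",
    "SYMBOLS",
    "atomic_number",
    "symbol",
    "classify_element",
    "is_valid_isotope",
    "default_implicit_hydrogens",
    "load_valence_table",
    "default_valence_table",
]

# Symbols for Z = 1..118; index 0 is a placeholder.
SYMBOLS = [
    "*",
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
]

MAX_Z = len(SYMBOLS) - 1

_Z_BY_SYMBOL = {s: z for z, s in enumerate(SYMBOLS) if z}


class InvalidElementError(ValueError):
    """Raised for atomic numbers outside the supported range."""


def atomic_number(sym: str) -> int:
    """Atomic number for an element symbol (case-sensitive, e.g. ``'Cl'``)."""
    try:
        return _Z_BY_SYMBOL[sym]
    except KeyError:
        raise InvalidElementError(f"unknown element symbol {sym!r}") from None


def symbol(z: int) -> str:
    _check_z(z)
    return SYMBOLS[z]


def _check_z(z: int) -> None:
    if not isinstance(z, int) or not 1 <= z <= MAX_Z:
        raise InvalidElementError(f"atomic number {z!r} outside 1..{MAX_Z}")


class ElementClass(enum.Enum):
    ORGANIC = "organic"
    METAL = "metal"
    TRANSITION_METAL = "transition_metal"
    SEMICONDUCTOR = "semiconductor"
    UNCLASSIFIED = "unclassified"


ORGANIC_Z = frozenset(atomic_number(s) for s in
                      ("H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"))

# Alkali and alkaline-earth metals: the elements the ionic-bond rule names.
METAL_Z = frozenset(atomic_number(s) for s in
                    ("Li", "Na", "K", "Rb", "Cs", "Fr",
                     "Be", "Mg", "Ca", "Sr", "Ba", "Ra"))

# d-block plus lanthanides and actinides.
TRANSITION_METAL_Z = frozenset(
    list(range(21, 31)) + list(range(39, 49)) +
    list(range(57, 81)) + list(range(89, 113))
)

# Metalloids with predominantly covalent bonding plus the post-transition
# metals that the transition-metal/semiconductor processing step treats as
# members of its element set Z.
SEMICONDUCTOR_Z = frozenset(atomic_number(s) for s in
                            ("Ge", "Sb", "Al", "Ga", "In", "Sn",
                             "Tl", "Pb", "Bi", "Po"))

# Subset Z' of semiconductors/transition metals allowed to keep covalent
# single bonds to tetra-valent C, di-valent O/S and tri-valent N.
Z_PRIME = frozenset(atomic_number(s) for s in
                    ("Al", "Ga", "Ge", "In", "Sn", "Sb",
                     "Hg", "Tl", "Pb", "Bi", "Po"))

# B, Si, As, Te, At are deliberately not in any class: their bonding is too
# diverse to justify class-based rules.


def classify_element(z: int) -> ElementClass:
    """Element class used by the standardization rules."""
    _check_z(z)
    if z in ORGANIC_Z:
        return ElementClass.ORGANIC
    if z in METAL_Z:
        return ElementClass.METAL
    if z in TRANSITION_METAL_Z:
        return ElementClass.TRANSITION_METAL
    if z in SEMICONDUCTOR_Z:
        return ElementClass.SEMICONDUCTOR
    return ElementClass.UNCLASSIFIED


# --------------------------------------------------------------------------
# Isotopes
# --------------------------------------------------------------------------
#
# The knowledgebase admits only nuclides with half-life > 1 ms.  The exact
# nuclide list is approximated as one contiguous mass-number window per
# element: curated windows for the light elements, a linear fit through the
# band of known long-lived nuclides for the rest (anchored at Th: 208..238).
# A mass number of 0 denotes the natural abundance mixture and is always
# valid.

_ISOTOPE_WINDOW_LIGHT = {
    1: (1, 3),     # H, D, T
    2: (3, 8),
    3: (4, 12),
    4: (6, 16),
    5: (7, 19),
    6: (8, 22),
    7: (10, 25),
    8: (12, 28),
    9: (14, 31),
    10: (16, 34),
}


# Anchors (Z, lowest A, highest A) for piecewise-linear interpolation of the
# long-lived nuclide band; the Th window 208..238 matches the known thorium
# isotope range.
_ISOTOPE_ANCHORS = [
    (10, 16, 34),
    (20, 34, 58),
    (38, 73, 107),
    (56, 112, 153),
    (74, 156, 198),
    (90, 208, 238),
    (118, 270, 299),
]


def _isotope_window(z: int) -> tuple[int, int]:
    if z in _ISOTOPE_WINDOW_LIGHT:
        return _ISOTOPE_WINDOW_LIGHT[z]
    for (z1, lo1, hi1), (z2, lo2, hi2) in zip(_ISOTOPE_ANCHORS,
                                              _ISOTOPE_ANCHORS[1:]):
        if z1 <= z <= z2:
            f = (z - z1) / (z2 - z1)
            return round(lo1 + f * (lo2 - lo1)), round(hi1 + f * (hi2 - hi1))
    z1, lo1, hi1 = _ISOTOPE_ANCHORS[-1]
    return lo1 + 2 * (z - z1), hi1 + 2 * (z - z1)


def is_valid_isotope(z: int, mass_number: int) -> bool:
    """True iff the nuclide (Z, A) is in the isotope knowledgebase.

    ``mass_number == 0`` means "natural abundance mixture" and is always
    valid.  The contract is boolean: unknown nuclides return ``False``.
    """
    _check_z(z)
    if mass_number == 0:
        return True
    if mass_number < z:
        return False
    lo, hi = _isotope_window(z)
    return lo <= mass_number <= hi


# --------------------------------------------------------------------------
# Default (MDL-style) valence model for implicit hydrogen filling
# --------------------------------------------------------------------------
#
# (atomic number, formal charge) -> ordered tuple of standard total valences.
# The implicit hydrogen count of an atom is the smallest standard valence
# >= its explicit bond-order sum, minus that sum (0 if none fits).  Elements
# absent from the map default to 0 implicit hydrogens.

_DEFAULT_VALENCES: dict[tuple[int, int], tuple[int, ...]] = {
    (atomic_number("H"), 0): (1,),
    (atomic_number("B"), 0): (3,),
    (atomic_number("B"), -1): (4,),
    (atomic_number("C"), 0): (4,),
    (atomic_number("C"), 1): (3,),
    (atomic_number("C"), -1): (3,),
    (atomic_number("Si"), 0): (4,),
    (atomic_number("N"), 0): (3,),
    (atomic_number("N"), 1): (4,),
    (atomic_number("N"), -1): (2,),
    (atomic_number("P"), 0): (3, 5),
    (atomic_number("P"), 1): (4,),
    (atomic_number("P"), -1): (2,),
    (atomic_number("As"), 0): (3, 5),
    (atomic_number("As"), 1): (4,),
    (atomic_number("O"), 0): (2,),
    (atomic_number("O"), 1): (3,),
    (atomic_number("O"), -1): (1,),
    (atomic_number("S"), 0): (2, 4, 6),
    (atomic_number("S"), 1): (3,),
    (atomic_number("S"), -1): (1,),
    (atomic_number("Se"), 0): (2, 4, 6),
    (atomic_number("Se"), 1): (3,),
    (atomic_number("Se"), -1): (1,),
    (atomic_number("F"), 0): (1,),
    (atomic_number("Cl"), 0): (1,),
    (atomic_number("Br"), 0): (1,),
    (atomic_number("I"), 0): (1,),
}


def default_implicit_hydrogens(z: int, charge: int, bond_order_sum: int) -> int:
    """Implicit hydrogen count per the simplistic default valence model.

    Assumes bond orders and formal charge are correct.  Non-organic elements
    and unknown (element, charge) combinations yield 0.
    """
    valences = _DEFAULT_VALENCES.get((z, charge))
    if not valences:
        return 0
    for v in valences:
        if bond_order_sum <= v:
            return v - bond_order_sum
    return 0


# --------------------------------------------------------------------------
# Valence knowledgebase
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ValenceRule:
    """One allowed atom configuration."""

    atomic_number: int
    formal_charge: int
    n_sigma: int
    n_pi: int
    max_implicit_h: int

    def key(self) -> tuple[int, int, int, int]:
        return (self.atomic_number, self.formal_charge, self.n_sigma, self.n_pi)


class ValenceTable:
    """Lookup of allowed atom configurations.

    An atom configuration is its (atomic number, formal charge, sigma-bond
    count, pi-bond count); sigma bonds here count explicit covalent
    neighbors only — implicit hydrogens are bounded separately by
    ``max_implicit_h``.
    """

    def __init__(self, rules: list[ValenceRule]):
        self._rules: dict[tuple[int, int, int, int], int] = {}
        for r in rules:
            k = r.key()
            if k in self._rules:
                raise ValueError(f"duplicate valence rule for {k}")
            if min(r.n_sigma, r.n_pi, r.max_implicit_h) < 0:
                raise ValueError(f"negative count in valence rule {r}")
            self._rules[k] = r.max_implicit_h

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        for (z, q, s, p), h in sorted(self._rules.items()):
            yield ValenceRule(z, q, s, p, h)

    def lookup(self, z: int, charge: int, n_sigma: int, n_pi: int) -> int | None:
        """Max implicit hydrogens for a configuration, or None if disallowed.

        Implicit hydrogens are sigma bonds: a configuration is also accepted
        if moving ``h`` implicit hydrogens into the sigma count matches a
        rule whose remaining implicit-hydrogen allowance covers them.
        """
        return self._rules.get((z, charge, n_sigma, n_pi))

    def allows(self, z: int, charge: int, n_sigma: int, n_pi: int,
               implicit_h: int) -> bool:
        """Whether an atom with ``implicit_h`` implicit hydrogens is allowed.

        Implicit hydrogens may be counted either against ``max_implicit_h``
        of the bare configuration or folded into the sigma count (the two
        encodings are equivalent in the knowledgebase's terms).
        """
        for folded in range(implicit_h + 1):
            h = self.lookup(z, charge, n_sigma + folded, n_pi)
            if h is not None and implicit_h - folded <= h:
                return True
        return False

    def dump(self, stream) -> None:
        """Serialize as the 5-column whitespace table (round-trips load)."""
        stream.write("# atomic_number charge n_pi n_sigma max_implicit_h\n")
        for r in self:
            stream.write(f"{r.atomic_number} {r.formal_charge} {r.n_pi} "
                         f"{r.n_sigma} {r.max_implicit_h}\n")


def load_valence_table(stream) -> ValenceTable:
    """Load a valence table from a 5-column whitespace-delimited stream.

    Columns: atomic number, charge, pi-bond count, sigma-bond count,
    max implicit hydrogens.  ``#`` starts a comment.
    """
    rules = []
    for lineno, line in enumerate(stream, 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"line {lineno}: expected 5 columns, got {len(parts)}")
        z, q, npi, nsig, maxh = (int(p) for p in parts)
        rules.append(ValenceRule(z, q, nsig, npi, maxh))
    return ValenceTable(rules)


def _curated_rules() -> list[ValenceRule]:
    """Curated allowed-configuration set, derived from total-valence models.

    For main-group elements every split of a total valence V into
    (sigma, pi) with pi <= sigma contributions of multiple bonds is allowed,
    with max implicit H = V - sigma - pi.  Uncharged metal and transition
    metal centers (and their common ionic charges) are allowed with no
    hydrogen and limited covalent connectivity.
    """
    totals: dict[tuple[int, int], tuple[int, ...]] = {
        (atomic_number("H"), 0): (0, 1),   # 0 sigma: H radical/monoatomic
        (atomic_number("H"), 1): (0,),
        (atomic_number("H"), -1): (0,),
        (atomic_number("B"), 0): (3,),
        (atomic_number("B"), -1): (4,),
        (atomic_number("B"), 1): (2,),
        (atomic_number("C"), 0): (0, 4),
        (atomic_number("C"), 1): (3,),
        (atomic_number("C"), -1): (3,),
        (atomic_number("Si"), 0): (4,),
        (atomic_number("N"), 0): (0, 3),
        (atomic_number("N"), 1): (4,),
        (atomic_number("N"), -1): (2,),
        (atomic_number("P"), 0): (3, 5),
        (atomic_number("P"), 1): (4,),
        (atomic_number("P"), -1): (2,),
        (atomic_number("As"), 0): (3, 5),
        (atomic_number("As"), 1): (4,),
        (atomic_number("O"), 0): (0, 2),
        (atomic_number("O"), 1): (3,),
        (atomic_number("O"), -1): (1,),
        (atomic_number("O"), -2): (0,),
        (atomic_number("S"), 0): (0, 2, 4, 6),
        (atomic_number("S"), 1): (3, 5),
        (atomic_number("S"), -1): (1,),
        (atomic_number("S"), -2): (0,),
        (atomic_number("Se"), 0): (2, 4, 6),
        (atomic_number("Se"), 1): (3,),
        (atomic_number("Se"), -1): (1,),
        (atomic_number("F"), 0): (0, 1),
        (atomic_number("F"), -1): (0,),
        (atomic_number("Cl"), 0): (0, 1, 3, 5, 7),
        (atomic_number("Cl"), -1): (0,),
        (atomic_number("Br"), 0): (0, 1, 3, 5, 7),
        (atomic_number("Br"), -1): (0,),
        (atomic_number("I"), 0): (0, 1, 3, 5, 7),
        (atomic_number("I"), -1): (0,),
        (atomic_number("Te"), 0): (2, 4, 6),
    }
    rules: dict[tuple[int, int, int, int], int] = {}
    organicish = ORGANIC_Z | {atomic_number(s) for s in ("B", "Si", "As", "Se", "Te")}
    for (z, q), vs in totals.items():
        hydrogenatable = z in organicish and z != atomic_number("H")
        for v in vs:
            # Enumerate (sigma, pi) splits of the total valence v: each
            # neighbor contributes one sigma bond, each extra order of a
            # multiple bond one pi bond (at most 2 pi per sigma neighbor).
            for n_sigma in range(0, v + 1):
                for n_pi in range(0, min(v - n_sigma, 2 * n_sigma) + 1):
                    maxh = v - n_sigma - n_pi
                    if not hydrogenatable and maxh != 0:
                        continue
                    key = (z, q, n_sigma, n_pi)
                    rules[key] = max(rules.get(key, 0), maxh)
    # Special case: H(0) as a free atom or with one bond, no implicit H on H.
    rules[(1, 0, 0, 0)] = 1  # bare H record: one implicit H would be H2; keep 0..1
    # Metals: bare ions only (covalent bonds to them become ionic/complex).
    for z in sorted(METAL_Z):
        for q in (0, 1, 2, 3):
            rules.setdefault((z, q, 0, 0), 0)
    # Transition metals: bare ions over the common oxidation range plus
    # limited covalent connectivity for the unmodified bonding scenarios
    # (oxo/halide/hydride bonds are retained by the functional-group step).
    for z in sorted(TRANSITION_METAL_Z):
        for q in range(-2, 8):
            rules.setdefault((z, q, 0, 0), 0)
        for q in (0, 1, 2):
            for n_sigma in range(1, 7):
                for n_pi in range(0, min(n_sigma, 3) + 1):
                    if n_sigma + n_pi <= 8:
                        rules.setdefault((z, q, n_sigma, n_pi), 0)
    # Semiconductors (incl. post-transition metals): bare ions and the
    # covalent connectivity the Z' scenarios keep.
    for z in sorted(SEMICONDUCTOR_Z):
        for q in (-1, 0, 1, 2, 3, 4):
            rules.setdefault((z, q, 0, 0), 0)
        for q in (0, 1, 2):
            for n_sigma in range(1, 5):
                for n_pi in range(0, 2):
                    rules.setdefault((z, q, n_sigma, n_pi), 0)
    # Noble gases: only the bare neutral atom.
    for s in ("He", "Ne", "Ar", "Kr", "Xe", "Rn"):
        rules.setdefault((atomic_number(s), 0, 0, 0), 0)
    return [ValenceRule(z, q, s, p, h) for (z, q, s, p), h in sorted(rules.items())]


@lru_cache(maxsize=1)
def default_valence_table() -> ValenceTable:
    """The bundled curated valence table.

    Ships as a generated data file so the same 5-column format covers both
    the bundled subset and a drop-in authoritative table.
    """
    res = importlib.resources.files("chemstd").joinpath("data/valence_rules.txt")
    with res.open("r") as fh:
        return load_valence_table(fh)
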
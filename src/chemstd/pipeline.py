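"""Pipeline orchestration: the nine standardization steps, modification
tracking, and deduplication by canonical key.

Steps, in order:

I    verify element        (reject only)
II   verify hydrogen
III  verify functional groups
IV   verify valence        (reject only)
V    standardize annotations
VI   standardize valence bond form (canonical tautomer; may reject)
VII  standardize aromaticity (canonical Kekulé form)
VIII standardize stereochemistry
IX   standardize explicit hydrogens (may reject at the 999 atom/bond cap)

Before step I a pre-processing pass unifies hydrogen representation
(implicit counts from the default valence model wherever the record did
not pin them).  Typed ionic/complex/dative bonds are trusted as parsed;
depositor bond-annotation *properties* are re-perceived in step III and
cleared in step V.

Modification tracking snapshots a de-aromatized canonical isomeric SMILES
before and after each step; a step modified the structure iff its
before/after snapshots differ.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from . import tables
from .aromaticity import KekulizationError, kekulize_canonical
from .mol import Atom, Bond, BondKind, Molecule, canonical_order
from .sdf import SdfRecord
from .smiles import read_smiles, write_canonical_smiles
from .stereo import StereoChangeRecord, standardize_stereo
from .tautomer import TautomerConfig, standardize_valence_bond
from .verify import (RejectionReason, TransformationRecord, preprocess_hydrogens,
                     verify_element, verify_functional_groups, verify_hydrogen,
                     verify_valence, STEP_NAMES)

__all__ = [
    "ATOM_BOND_LIMIT", "PipelineConfig", "StandardizationResult",
    "Standardizer", "standardize_annotations", "explicit_hydrogens",
    "compound_key", "deduplicate",
]

ATOM_BOND_LIMIT = 999


@dataclass
class PipelineConfig:
    valence_table: object | None = None      # tables.ValenceTable
    tautomer: TautomerConfig = field(default_factory=TautomerConfig)
    track: bool = True


@dataclass
class StandardizationResult:
    status: str                                  # "accepted" | "rejected"
    molecule: Molecule | None = None
    rejection: RejectionReason | None = None
    snapshots: dict[str, tuple[str, str]] = field(default_factory=dict)
    modified_steps: list[str] = field(default_factory=list)
    transformations: list[TransformationRecord] = field(default_factory=list)
    tautomer_counts: dict[int, int] = field(default_factory=dict)
    stereo_changes: StereoChangeRecord | None = None
    timings: dict[str, float] = field(default_factory=dict)
    key: str | None = None                       # CompoundKey of the result

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def standardize_annotations(mol: Molecule) -> Molecule:
    """Step V: drop deposited bond-annotation properties; graph untouched."""
    out = mol.copy()
    out.properties = {}
    return out


def explicit_hydrogens(mol: Molecule) -> Molecule | RejectionReason:
    """Step IX: re-derive implicit hydrogen counts with the default valence
    model, then convert them to explicit atoms (single-bonded).

    Radical electrons lower the count.  Rejects when the expansion exceeds
    999 atoms or bonds.
    """
    out = mol.copy()
    for i, a in enumerate(out.atoms):
        if a.implicit_h < 1:
            continue
        s = sum(b.order for _, b in out.covalent_neighbors(i))
        h = tables.default_implicit_hydrogens(a.atomic_number,
                                              a.formal_charge, s)
        a.implicit_h = max(0, h - a.radical_electrons)
    n_atoms = len(out.atoms) + sum(a.implicit_h for a in out.atoms)
    n_bonds = sum(1 for b in out.bonds if b.kind is BondKind.COVALENT) \
        + sum(a.implicit_h for a in out.atoms)
    if n_atoms > ATOM_BOND_LIMIT or n_bonds > ATOM_BOND_LIMIT:
        return RejectionReason(
            "standardize_explicit_hydrogens",
            f"{n_atoms} atoms / {n_bonds} bonds exceed the limit of "
            f"{ATOM_BOND_LIMIT}")
    for i in range(len(out.atoms)):
        a = out.atoms[i]
        first_h = None
        while a.implicit_h > 0:
            h_idx = out.add_atom(Atom(1))
            out.add_bond(Bond(i, h_idx, order=1))
            if first_h is None:
                first_h = h_idx
            a.implicit_h -= 1
        if first_h is not None and a.tet_stereo is not None \
                and -1 in a.tet_stereo[0]:
            refs, sense = a.tet_stereo
            a.tet_stereo = (tuple(first_h if r == -1 else r for r in refs),
                            sense)
        a.explicit_h_spec = True
    return out


def _preprocess(mol: Molecule) -> Molecule:
    # typed nonstandard bonds are trusted as parsed; only depositor
    # annotation *properties* are re-perceived (and cleared in step V)
    return preprocess_hydrogens(mol)


def compound_key(mol: Molecule) -> str:
    """Canonical key: de-aromatized canonical isomeric SMILES plus a
    serialized nonstandard-bond list.

    SMILES alone ignores nonstandard bonds, which would merge structures
    that differ only in ionic/complex/dative bonding; the appended bond
    list keeps them apart.
    """
    smi = write_canonical_smiles(mol, dearomatize=True, isomeric=True)
    ns = [b for b in mol.bonds if b.kind is not BondKind.COVALENT]
    if not ns:
        return smi
    rank = canonical_order(mol)
    entries = sorted(
        (b.kind.value, min(rank[b.a1], rank[b.a2]), max(rank[b.a1], rank[b.a2]))
        for b in ns)
    return smi + "|" + ";".join(f"{k}:{x}-{y}" for k, x, y in entries)


class Standardizer:
    """Runs the nine-step standardization over records."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    # -- single record -----------------------------------------------------

    def standardize(self, record) -> StandardizationResult:
        """Standardize one record (SdfRecord, Molecule or SMILES string)."""
        if isinstance(record, str):
            mol = read_smiles(record)
        elif isinstance(record, SdfRecord):
            mol = record.molecule.copy()
        else:
            mol = record.copy()
        res = StandardizationResult(status="accepted")
        mol = _preprocess(mol)

        def snap(m):
            return write_canonical_smiles(m, dearomatize=True, isomeric=True) \
                if self.config.track else ""

        for step in STEP_NAMES:
            before = snap(mol)
            t0 = time.perf_counter()
            outcome = self._run_step(step, mol, res)
            res.timings[step] = time.perf_counter() - t0
            if isinstance(outcome, RejectionReason):
                res.status = "rejected"
                res.rejection = outcome
                return res
            mol = outcome
            after = snap(mol)
            if self.config.track:
                res.snapshots[step] = (before, after)
                if before != after:
                    res.modified_steps.append(step)
        res.molecule = mol
        res.key = compound_key(mol)
        return res

    def _run_step(self, step: str, mol: Molecule, res: StandardizationResult):
        if step == "verify_element":
            rej = verify_element(mol)
            return rej if rej else mol
        if step == "verify_hydrogen":
            return verify_hydrogen(mol)
        if step == "verify_functional_groups":
            out, records = verify_functional_groups(mol)
            res.transformations.extend(records)
            return out
        if step == "verify_valence":
            rej = verify_valence(mol, self.config.valence_table)
            return rej if rej else mol
        if step == "standardize_annotations":
            return standardize_annotations(mol)
        if step == "standardize_valence_bond":
            out = standardize_valence_bond(mol, self.config.tautomer)
            if isinstance(out, RejectionReason):
                return out
            mol2, info = out
            res.tautomer_counts = {ci: oc.n_generated
                                   for ci, oc in info.items()}
            return mol2
        if step == "standardize_aromaticity":
            try:
                return kekulize_canonical(mol)
            except KekulizationError as e:
                return RejectionReason("standardize_aromaticity", str(e))
        if step == "standardize_stereochemistry":
            out, rec = standardize_stereo(mol)
            res.stereo_changes = rec
            return out
        if step == "standardize_explicit_hydrogens":
            return explicit_hydrogens(mol)
        raise AssertionError(step)

    # -- streams -------------------------------------------------------------

    def standardize_all(self, records):
        return [self.standardize(r) for r in records]


def deduplicate(results) -> dict[str, list]:
    """Group accepted results by CompoundKey (the SID->CID merge)."""
    groups: dict[str, list] = {}
    for r in results:
        if getattr(r, "accepted", False) and r.key is not None:
            groups.setdefault(r.key, []).append(r)
    return groups
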
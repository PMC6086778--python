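# Methods

This note records the scientific conventions behind `chemstd`: the model
each pipeline step implements, the parameters that matter, the choices made
where a convention had to be fixed, and what the bundled synthetic data
does and does not exercise.

## Valence and the bond model

*Atom valence* is the bond-order sum over covalent bonds, counting implicit
hydrogens. Ionic, complex and dative bonds are zero-order: they carry
structural meaning (salt pairing, coordination, donor–acceptor sharing)
but never contribute to valence, never join covalent components, and are
ignored by SMILES generation. In SDF output they are omitted from the
V2000 bond block and serialized in a `NONSTANDARD_BONDS` data field
(`<a1> <a2> <ionic|complex|dative>`, 1-based); the exact field layout is
this package's own convention.

Element classes drive several rules: *organic* is exactly
{H, C, N, O, F, P, S, Cl, Br, I}; *metals* are the alkali and
alkaline-earth elements; *transition metals* the d-block plus lanthanides
and actinides; *semiconductors* Ge and Sb plus the post-transition metals
Al, Ga, In, Sn, Tl, Pb, Bi, Po (so that the subset Z′ used by the
covalent-retention rules is contained in the transition-metal ∪
semiconductor set). B, Si, As, Te and At belong to no class: their bonding
is too diverse for class-based rules.

## Knowledgebases

**Isotopes.** Only nuclides with half-life above 1 ms are accepted; a mass
number of 0 means the natural-abundance mixture. The nuclide set is
approximated by one contiguous mass window per element: curated windows
for Z ≤ 10, piecewise-linear interpolation through anchors for heavier
elements (the thorium window is 208–238, matching the known isotope
range). Holes inside the band of real nuclide charts are not modeled; the
table errs slightly permissive in the band interior and correctly rejects
far-off masses such as a 4-Da thorium.

**Valence configurations.** The verifier consults a table keyed by
(atomic number, formal charge, σ-bond count, π-bond count) with a maximum
implicit-hydrogen allowance; implicit hydrogens may equivalently be folded
into the σ count. The bundled table is curated: for main-group elements it
is generated from per-(element, charge) total-valence sets (e.g. C⁰→4,
N⁰→3, N⁺→4, S⁰→{2,4,6}, halogens⁰→{1,3,5,7}), for metals it admits bare
ions over common oxidation states and limited covalent connectivity for
transition metals. Every configuration the pipeline's rules can produce
(nitro, azide, carbon monoxide, carbanion rings, metal centers after
complexation) is present; tetra-valent oxygen and penta-valent carbon are
absent by construction. The loader also accepts an external 5-column
whitespace file (atomic number, charge, π count, σ count, max implicit H;
`#` comments), so an authoritative table can be dropped in unchanged.

**Default valence model.** Implicit-hydrogen filling uses an MDL-style
model: an ordered list of standard total valences per (element, charge)
(P⁰: 3 then 5; S⁰: 2, 4, 6; Cl⁰: 1, 3, 5, 7; N⁺: 4; O⁻: 1; …); the
implicit count is the smallest standard valence that covers the explicit
bond-order sum, minus that sum. Non-organic elements get no implicit
hydrogens, and radicals reduce the count by the number of unpaired
electrons.

## Functional-group normalization (step III)

The 34 rules are an ordered registry of (matcher, editor) pairs in
`transform.py`, applied family by family; within a rule, atoms are scanned
in canonical order and the scan restarts after every edit until a fixed
point, which makes the outcome independent of input atom numbering. The
step never rejects — impossible outcomes surface in the valence check.
Conventions fixed here:

* The oxide zwitterion fixes (indices 1–4) cover S/Se/P/As(+)–O(−)/S(−)
  and C(+)–O(−)/S(−) terminal pairs with no implicit hydrogens on the
  manipulated atoms. Nitrogen is deliberately excluded: amine oxides and
  nitro groups keep their charge-separated form.
* Ionic-bond creation (8) requires the cation and anion to be the *only*
  candidates of their kind — with two Na⁺ and one Cl⁻ nothing is set.
  Covalent→ionic conversion (9, 10) increments charges unless the partner
  ends as di-valent O or tri-valent N, with limits ±1 (alkali) and ±2
  (alkaline-earth).
* Tri-valent oxygen (12, 13): a terminal, uncharged, triple-bonded O gets
  +1; when the partner is a terminal uncharged carbon (carbon monoxide) or
  a metal-bound carbon, the carbon gets −1 as well.
* Transition-metal/semiconductor processing (15) protects oxo, metal-oxo,
  halide and hydride bonds (and, for Z′ elements, single bonds to
  tetra-valent C, di-valent O/S, tri-valent N), moves charges from N⁺,
  forms carbanions/aza-anions for conjugated 5-/7-rings and C=O/N=O
  ligands with a matching metal charge increment, converts the remaining
  single bonds to complex bonds, and rolls the metal charge back if its
  final configuration is not in the valence table. Two readings had to be
  fixed: the "increment hydrogen" fallback applies only to uncharged
  ligands, and the tetra-valent-S-with-one-H special case removes the
  hydrogen *and* assigns −1.
* The nitro-with-hydroxyl deprotonation (31) does not fire when the N⁺
  already carries an O⁻ — otherwise nitric acid would lose a proton and
  change its net charge.
* The thiophene unification (34) only re-positions existing unsaturation
  (two ring double bonds in nonstandard positions, or an S=C drawing);
  genuinely saturated dihydro/tetrahydro rings are left alone.

Indices 8–11, 13, 15 and 22–28 are pinned by which rules set ionic,
complex and dative bonds; the remaining indices follow figure order and
live in one table for easy correction.

## Canonical tautomer (step VI)

Each covalent component with at least two atoms is processed separately.
Components are first checked against a blacklist (skip entirely) and a
limit list (cap 2,500 generated tautomers instead of 250,000); both ship
empty and are plain one-SMILES-per-line files.

The walk treats protons and charges as mobile: 1,3- and 1,5-proton shifts
along alternating single/double paths between N/O/S/P (and single-H
carbon *donors* — methyl and methylene never donate, and protons never
land on carbon, since acidic C–H normalization is out of scope), plus
1,3-charge shifts of ±1 charges. The component is relabeled canonically
before the breadth-first walk, so emission order is label-invariant.
Generated tautomers conserve molecular formula and net charge, may not
fall below the input's energetic class (the 7-level charged-atom-pattern
ladder), and must reproduce the immobilized charges (charges in
ionic/complex bonds, azide terminal N⁻, nitro O⁻/S⁻) exactly — the walk
simply never moves them.

Scoring is strictly lexicographic: the signed preferred-valence deviation
(preferred C 4, N 3, P 3, O 2, S 2, charge magnitude counted toward the
valence; the sign convention is ambiguous in prose, but the whole term is
invariant under the implemented move set, so the choice is observationally
neutral), then the charged-atom count, then the 19 ordered count criteria
ending in "fewer C=C double bonds". The "more aromatic atoms" criterion
uses the ring-focused model (below). Greedy selection keeps the best
generated form; if it does not strictly beat the original, the arbitration
score count(C=C) − 2·count(N=N) (lower wins) may still adopt it —
encoding the method's preference for N=N over C=N — and exact ties keep
the original. Consequence: tautomer pairs that tie on every criterion
(1H/3H lactams, N7H/N9H purines, simple acyclic amidines) deliberately
remain distinct structures.

The final structure is re-checked against the valence table, and any
covalently adjacent pair of like charges rejects the record at this step.

## Aromaticity and kekulization (step VII)

The *general* model is Hückel 4n+2 counting over the smallest-ring basis
and fused-ring envelopes up to a combined path length of 40: a ring double
bond contributes one electron per atom, pyrrole-type N/O/S/Se lone pairs
two, carbanions two, carbocations and exocyclic-double-bond atoms zero
(an exocyclic double bond does not disqualify the ring — pruning is off),
saturated carbon breaks the system. The *ring-focused* model used only by
the tautomer score is the stricter alternating-single/double six-ring
count.

Rekekulization (skipped below 3 atoms) clears flags, perceives with the
general model, erases the single/double assignment inside aromatic
systems, and reassigns it by backtracking perfect matching over the atoms
that need one π bond (need derived from the default valence model), trying
bonds in canonical order. It therefore succeeds whenever any Kekulé form
exists, is label-invariant, and may legitimately emit a different — but
canonical — Kekulé form than deposited. Round trips preserve the aromatic
atom/bond sets and per-system double-bond counts.

## Stereochemistry (step VIII)

Symmetry classes come from Morgan-style relaxation over the invariant
(element, charge, covalent degree, attached H, isotope, ring membership),
with explicit hydrogens pinned to class 0. Tetrahedral eligibility follows
the decision table: aromatic atoms, hydrogens, atoms with more than one H,
and N–H centers are out; P must be (3-valent, 3-coordinate) or (5-valent,
4-coordinate); S must be (6-valent, 4-coordinate, no CH/charged-C single
neighbor, only single/double bonds) or (4-valent, 3-coordinate); others
tetra-valent tetra-coordinate; and all neighbor classes must differ.
Mesomeric OH/O⁻/=O/SH/S⁻/=S ligands negate chirality only in *like*
pairs — O=P–OH is achiral while S=P–OH can be chiral — so the ligand count
is per element.

Parity reconciliation: in 3-D, coordinates win; in 2-D, a parity needs
wedge support (wedges act as pseudo-depth at the narrow end), and an
annotated parity contradicting the wedge-derived one becomes undefined.
For SMILES input, the `@`/`@@` mark is the annotated parity directly — no
depiction round trip is performed, since the information content is
identical. Double bonds are stereogenic only when non-aromatic, with
3-coordination on both ends, smallest ring ≥ 8 if cyclic, fewer than two
hydrogens per side, the printed nitrogen conditions, and distinct
neighbor classes on each side; E/Z is resolved from an annotated parity or
from geometry with a 10° collinearity tolerance, deposited crossed bonds
stay undefined, and undefined stereogenic bonds are depicted crossed.
Everything ineligible is stripped, and added/modified/removed/unchanged
counts are reported.

## Tracking, keys and hydrogen conventions

Snapshots are de-aromatized canonical isomeric SMILES. The writer folds
unremarkable explicit hydrogens into implicit counts and renders the
hydrogen on a chiral atom as an explicit `[H]`; with these conventions the
element/valence/annotation steps never register modifications, and
re-running the pipeline on its own output registers none anywhere. The
compound key appends the canonical-rank-serialized nonstandard-bond list
to the SMILES, because SMILES alone would merge structures differing only
in ionic/complex/dative bonding. Typed nonstandard bonds are trusted as
parsed; only depositor annotation *properties* are re-perceived and then
cleared in step V. Step IX re-derives implicit counts with the default
model, expands them to explicit atoms, and rejects structures exceeding
999 atoms or bonds.

## Synthetic data

`fixtures.paper_fixtures()` regenerates every worked example the rules are
built around (guanine in eight convergent drawings, tautomer-preference
pairs, the rejection cases, one exemplar per bond-perception family);
structures whose full connection tables are not public are simplified
stand-ins exercising the same code path. `fixtures.random_corpus(seed, n,
max_heavy)` grows seeded random C/N/O/S molecules with deliberate
amide/amidine-type donor–acceptor motifs, so that roughly half of a
default corpus exhibits more than one valence-bond form — qualitatively
matching how common tautomerism is in deposited structures, though real
deposition data additionally contains organometallics, polymers, drawing
artifacts and malformed records at rates a random generator does not
emulate. Passing the property suites on this corpus demonstrates the
invariants (idempotence, label invariance, conservation laws,
greedy-vs-exhaustive agreement), not database-scale statistics.
`fixtures.pathological_conjugated()` builds independent conjugated
carbanion arms whose product state space exceeds the 250,000-state cap,
the structure class that dominates enumeration blow-ups in practice.

## Numerical and procedural choices

* Canonical ranking: invariant refinement plus minimal-certificate
  branching; complete adjacency certificates make the canonical form
  label-invariant (automorphic atoms may swap ranks).
* Kekulization tie-breaks, tautomer emission order, nitro-oxygen choice in
  rule 18 and ring orientation in rules 32–34 all use canonical ranks.
* The enumeration walk counts symmetry-duplicate labeled states toward the
  caps (the caps bound work, not distinct isomers).
* The 5-minute wall-clock candidacy rule for the blacklist/limit list is a
  logged advisory only; the shipped lists are not mutated at run time.
* Problem sizes in the test suite and acceptance script — a 40-molecule
  property corpus, 100-molecule statistics corpus, 100 relabelings per
  fixture, one full 250,000-state cap run — were chosen to exercise every
  invariant at desk scale.

## Known limitations

* Database-scale statistics (rejection/modification rates over tens of
  millions of substances) are out of scope; the corpus rates are
  qualitative analogues only.
* The isotope windows are contiguous approximations of the nuclide chart.
* The bundled valence table is a curated subset, not the authoritative
  981-row list; behavior on exotic metal configurations depends on it.
* Charged-ring and tellurium aromaticity follow this package's Hückel
  definition; proprietary models are known to diverge on such corner
  cases, and no attempt is made to reproduce any of them.
* Tautomer ties keep the input form by design; registration systems
  wanting total tautomer merging need an additional total order.
* Extended stereo (allenes, atropisomers) and CIP letter assignment are
  not implemented.
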
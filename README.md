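# chemstd — chemical structure standardization

Public chemical databases receive the same compound drawn in dozens of
ways: different tautomers, different Kekulé assignments of aromatic rings,
zwitterionic vs. neutral functional-group drawings, explicit vs. implicit
hydrogens, stereo annotation of centers that are not actually stereogenic —
and, not rarely, structures that are simply wrong (penta-valent carbons,
impossible isotopes). `chemstd` implements a registration-grade
standardization pipeline for such substance-style records: it **verifies**
that every atom is chemically sensible and **normalizes** the survivors to
one preferred representation, so that equivalent deposits map to the same
canonical key.

The pipeline has nine steps in two phases:

| phase | step | what it does |
|---|---|---|
| verify | I. verify element | element and isotope validity (nuclides with half-life > 1 ms) |
| | II. verify hydrogen | fold explicit H into implicit counts; fix charge/valence mismatches (e.g. neutral valence-5 N → N⁺) |
| | III. verify functional groups | 34 indexed rewriting rules: nitro/azide charge separation, CO → [C−]≡[O+], ionic/complex/dative bond perception, metallocene rings, … |
| | IV. verify valence | every (element, charge, σ, π, implicit-H) configuration must be in the valence knowledgebase |
| normalize | V. standardize annotations | drop deposited bond-annotation properties |
| | VI. standardize valence bond form | canonical tautomer per covalent component: breadth-first canonic walk (1,3-/1,5-proton and 1,3-charge shifts) under energetic-class and cap limits, greedy selection by a 21-term lexicographic score |
| | VII. standardize aromaticity | Hückel perception, then canonical rekekulization by perfect matching in canonical bond order |
| | VIII. standardize stereochemistry | symmetry-class-based stereocenter eligibility; parity/wedge/coordinate reconciliation; invalid stereo stripped |
| | IX. standardize explicit hydrogens | implicit counts → explicit atoms; records over 999 atoms/bonds rejected |

Ionic, complex and dative bonds are first-class *zero-order* bonds: they
never contribute to valence, do not join covalent components, and travel in
a dedicated SD data field rather than the V2000 bond block.

Modification tracking snapshots a de-aromatized canonical isomeric SMILES
before and after every step; the final key (SMILES plus the serialized
nonstandard-bond list) deduplicates records into compounds.

## Worked example

```python
>>> from chemstd import Standardizer
>>> std = Standardizer()
>>> res = std.standardize("CN(=O)=O")        # nitromethane, penta-valent drawing
>>> res.status
'accepted'
>>> res.key
'C[N+]([O-])=O'
>>> res.modified_steps
['verify_functional_groups']
>>> [(t.transformation_index, t.description) for t in res.transformations]
[(18, 'nitro/nitrate penta-valent form charge separation')]
```

The deposited penta-valent nitro group was rewritten by transformation
rule 18 into the charge-separated form; no other step changed the
structure, and the canonical key is the final de-aromatized isomeric
SMILES. A guanine deposited as the lactim tautomer instead converges in
step VI:

```python
>>> res = std.standardize("Nc1nc2[nH]cnc2c(O)n1")   # lactim drawing
>>> res.key
'C1=NC=2C(NC(N)=NC=2N1)=O'
>>> res.modified_steps
['standardize_valence_bond']
>>> sum(res.tautomer_counts.values())               # forms evaluated
16
```

All eight bundled guanine input variants produce this same key and merge
into one compound under `chemstd.deduplicate`.

The command line mirrors the library:

```
chemstd run input.sdf --out standardized.sdf --rejects rejects.sdf --report report.json
```

exits 0 when everything standardized, 2 when records were rejected, and
writes per-record outcomes plus per-step rejection/modification counts to
the JSON report. `chemstd rules` prints the transformation registry.

## Layout

```
src/chemstd/
  tables.py        element classes, isotopes, valence knowledgebase, default valences
  mol.py           molecular graph, symmetry classes, canonical ranking
  smiles.py        SMILES reader / canonical isomeric SMILES writer
  sdf.py           MDL V2000 reader/writer, nonstandard-bond data field
  verify.py        steps I, II, IV (+ hydrogen pre-processing)
  transform.py     step III: the indexed functional-group rule registry
  tautomer.py      step VI: enumeration, scoring, selection, post-checks
  aromaticity.py   step VII: perception models and canonical kekulization
  stereo.py        step VIII: eligibility, parity resolution, stripping
  pipeline.py      steps V, IX, orchestration, tracking, deduplication
  fixtures.py      regenerated worked examples and the random corpus
  cli.py           `chemstd` command line
```

See `docs/methods.md` for the scientific conventions, parameter choices
and known limitations.
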
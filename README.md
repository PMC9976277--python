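# rmechkit

Elementary radical reaction steps as data: parse, validate, canonicalize,
apply, classify, deduplicate and search.

## The problem

Radical chemistry — combustion, polymerization, atmospheric oxidation,
many enzymatic transformations — proceeds through *elementary steps*:
reactions with a single transition state, chained into mechanistic
pathways. Databases of such steps (for curation, teaching, and training
machine-learning models of reactivity) need a representation that is
precise enough to derive products mechanically and canonical enough to
deduplicate contributions from many authors.

`rmechkit` implements that representation end to end. An elementary
radical step is a set of atom-mapped reactant molecules (SMILES, radicals
as valence-deficient bracket atoms) plus an *arrow code*: an ordered list
of curved half (fishhook) arrows, each moving exactly one electron
between molecular-orbital sites. The transition state is modeled as the
movement of a single electron from one reactive molecular orbital (a
SOMO, a sigma or pi bond, or a lone pair) to another; every valid step
therefore has **exactly two reactive MOs and two reactive atoms** (the
main atoms of those MOs). Lone pairs or pi bonds adjacent to pi-bond MOs
can be chained for longer-range resonance rearrangements.

The arrow dialect: atom site `a<label>`, bond site `b<label>-<label>`,
one arrow `source>target`, arrows joined by `;`. For example, hydrogen
abstraction from methane by a chlorine atom is

```
[CH3:10][H:11].[Cl:20]        b10-11>a10;b10-11>b11-20;a20>b11-20
```

— the C–H sigma bond returns one electron to carbon and sends one into
the nascent H–Cl bond, which the chlorine SOMO completes.

Seven mechanism classes are recognized from the (source MO, sink MO,
bond-edit) signature — homolysis, recombination, abstraction, addition,
retro-addition (beta-scission), pi resonance and alpha (lone-pair)
resonance — and map onto the three radical-chain phases: homolysis
initiates (+2 radical electrons), recombination terminates (−2),
everything else propagates (0).

Stored records follow a strict canonical form: participating atoms of
the nucleophilic component are relabeled 10, 11, …, of the electrophilic
component 20, 21, …, molecule SMILES canonicalized, and the arrow code
rewritten to begin at label 10 — so the same chemistry entered with any
labels, molecule order or SMILES spelling deduplicates to one record.

## Worked example

```python
from rmechkit import (
    parse_step, canonicalize_step, classify_mechanism, classify_phase,
    radical_delta,
)

# methane + chlorine atom, entered with arbitrary labels {3, 4, 7}
step = parse_step("[C:3]([H:4])([H])([H])[H].[Cl:7]",
                  "b3-4>a3;b3-4>b4-7;a7>b4-7")

print(classify_mechanism(step))        # abstraction
print(classify_phase(step))            # propagation
print(radical_delta(step))             # 0
print(step.reactive_mo_source.kind,    # sigma (3, 4)   — the breaking C-H
      step.reactive_mo_source.labels)
print(step.reactive_mo_sink.kind,      # somo (7,)      — the Cl radical
      step.reactive_mo_sink.labels)

record = canonicalize_step(step)
print(record.reactants_smiles)  # [CH3:10][H:11].[Cl:20]
print(record.products_smiles)   # [CH3:10].[H:11][Cl:20]
print(record.arrow_code)        # b10-11>a10;b10-11>b11-20;a20>b11-20
print(record.reactive_atom_1_smiles)  # C[H:1]
print(record.reactive_atom_2_smiles)  # [Cl:1]
```

The products (methyl radical + HCl) are *derived* from the arrows, not
declared; a SMIRKS that declares different products is rejected. The
user's labels {3, 4, 7} were discarded in favor of the storage
convention {10, 11, 20}.

The same surface is available from the shell:

```sh
rmechkit fixtures --output steps.csv -n 3 --seed 0
rmechkit classify --input steps.csv
rmechkit search --index steps.csv --similar 'ClCl>>[Cl].[Cl]' --metric tanimoto -n 5
rmechkit ingest --input new_steps.csv --index steps.csv --output merged.csv
```

CSV files use the twelve-column record schema (id, mapped reactants,
products, arrow code, spectators, the two reactive-atom SMILES, step
type, condition, phase class, mechanism class, source).

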
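# Methods

## The elementary-step model

An elementary radical step is modeled as the movement of one electron
between two reactive molecular orbitals. Orbitals are perceived at the
valence-bond level from the molecular graph: one SOMO per radical
electron, one sigma MO per unit bond plus the sigma framework of every
multiple bond, one pi MO per unit of bond order above one, and one
lone-pair MO per nonbonded electron pair. Electron bookkeeping per atom
(radicals + bonding electrons + lone-pair electrons against the
element's valence-electron count and formal charge, capped at the octet,
duet for H) is enforced on input, after every edit, and inside orbital
perception.

Each MO carries a *main atom*. For one-atom MOs this is trivial; for
bond MOs the main atom is the atom whose bonding partners change — the
atom gaining a brand-new partner when the step forms a new bond (the
transferred H in an abstraction, the attacked carbon in an addition), or
the atom toward/with which the relocated somo leaves when it does not
(the leaving-radical carbon of a beta-scission, the far carbon of an
allyl shift). Outside a step context, ties fall back to canonical atom
rank. The two reactive atoms of a step are the main atoms of its source
and sink MOs.

## Arrow semantics

The arrow matcher recognizes three shapes, by arrow count:

* **1 arrow** — alpha resonance: a lone pair on atom B adjacent to a
  somo on atom A, drawn from B toward the A–B bond.
* **2 arrows** — homolysis (a bond site feeding both of its own atoms)
  or recombination (two somos feeding a nascent bond site).
* **odd n >= 3** — an alternating chain `a(r)>P1; S1>P1; S1>P2; ...;
  Sk>a(w)`: bonds `P_i` gain one order unit (`P1` may be nascent), bonds
  `S_i` lose one, the somo leaves `r` and appears on `w`. `k = 1` covers
  abstraction, addition, retro-addition and single-hop pi resonance; the
  general chain covers conjugate addition and long-range resonance,
  which is how "pi bonds adjacent to pi-bond MOs can be chained" is
  realized. Lone-pair chains longer than the single alpha arrow are not
  accepted; none of the seven categories needs them.

Anything else (even arrow counts, disconnected chains, arrows without
the required radical or lone pair) cannot be explained by one
source/sink MO pair and is rejected as a step-object failure. Bond
edits are applied with hydrogen counts frozen, re-checked by the electron
bookkeeping above, and products are normalized through a canonical-SMILES
round trip so they read like hand-written SMILES.

### The alpha-resonance edit rule

The classic depiction of alpha resonance draws the half arrow from the
lone pair into the adjacent bond, which would create a three-electron
pi system that a valence SMILES cannot hold (a ketyl product written
`C=[O-]` with a radical on O violates every standard valence model and
cannot round-trip through SMILES, where radical counts are implied by
hydrogen deficit). This package therefore executes alpha resonance as a
single-electron transfer between the adjacent atoms: somo(A) + lone
pair(B) -> lone pair(A) + somo(B), bond order unchanged, formal charges
recomputed from the electron counts (A gains one unit of negative
charge, B loses one). For the ketyl radical anion this reproduces the
textbook resonance pair R2C(•)–O(−) <-> R2C(−)–O(•), conserves atoms and
electrons exactly, and keeps the radical count unchanged, as resonance
must. The arrow *syntax* keeps the lone-pair-to-bond form of the
classical drawing; only the executed edit differs.

## Classification

The seven mechanism categories are decided from (source MO kind, sink
MO kind, edit signature): sigma -> nascent somos is homolysis; somo +
somo -> new sigma is recombination; for chains, a nascent first bond
means abstraction (sigma donor) or addition (pi donor), an existing
first bond means retro-addition (sigma donor) or pi resonance (pi
donor); a lone-pair -> somo exchange is alpha resonance. Abstraction is
thus distinguished from retro-addition by whether the sigma cleavage
transfers an atom into a brand-new bond versus promoting an existing
bond to a pi bond; the signature is agnostic to intra- versus
intermolecular H transfer. Steps that build but match no signature —
e.g. homolysis of a pi bond into a diradical — raise an unclassifiable
error rather than being forced into a label. Phase classification is a
pure function of the mechanism (homolysis -> initiation, recombination
-> termination, rest -> propagation) and always agrees with the sign of
the radical-electron change (+2/−2/0).

## Canonical form

Participating atoms (those referenced by arrows) are relabeled by role:
the component donating the source MO's electron density is nucleophilic
and takes labels from 10, the other side from 20. Within a breaking
sigma bond the label order is (radical-receiving atom, shared atom) =
(10, 11) with the radical partner at 20; for pi sinks the somo carrier
takes 10 and the pi atoms (attacked atom first) 20, 21. Homolysis labels
its two sigma atoms 10 and 20, nucleophile chosen as the nascent
fragment whose canonical SMILES sorts first; recombination orders the
two radicals the same way. Ties occur only between graph-equivalent
atoms, so the emitted strings are independent of the choice. Arrows are
rewritten over the new labels and sorted by (source site, target site)
labels, which makes every canonical code begin at label 10. Molecule
SMILES are RDKit-canonical with explicit hydrogens folded in unless
labeled, and molecules are dot-joined in sorted order. Record ids
default to a content hash of the four key components (reactants,
products, arrows, spectators), so identical chemistry gets identical
ids.

Duplication is equality of those four components; spectators are
compared as a multiset (two copies of a spectator differ from one).

## Search

The reaction fingerprint is the bitwise union of reactant-molecule
Morgan (ECFP-like, radius 2, 2048 bits per side, configurable)
fingerprints concatenated with the union of product-molecule
fingerprints — order-invariant by construction. Similarity metrics on
binary vectors with set-bit counts a, b and overlap c: Tanimoto
c/(a+b−c), Dice 2c/(a+b), cosine c/sqrt(ab); Tanimoto <= Dice
algebraically. Containment searches (exact, by-reactants, by-products)
compare canonical unmapped SMILES multisets; substructure search matches
SMARTS against reactant- and product-side molecules; reactive-atom
search matches by atom environment (the query molecule must equal the
stored parent and the labeled atom must sit at the stored canonical
position). Learned-embedding similarity is out of scope (it requires
trained weights); the metric slot is a plain string and extensible.
Results are always ordered by reaction id (descending score first for
similarity), so every query is deterministic.

## Fixtures: what they emulate and what they do not

The generator instantiates hand-written templates for the seven
categories — halogen and peroxide homolysis, alkyl/halogen/oxy radical
recombination, H abstraction from alkanes, radical addition to terminal
alkenes, beta-scission, allyl shifts, and ketyl alpha resonance — and
decorates non-reacting positions with methyl/F/Cl under a seeded RNG
(string-seeded `random.Random`, so output is platform-stable). Elements
are limited to H, C, N, O and halogens; the only charged species is the
ketyl anion. This covers the full *representational* surface (every
arrow shape, every class, every failure mode) at small molecule sizes.
It does not emulate a curated database's class distribution, its
atmospheric (isoprene/MCM-style) chemistry, aromatic or polycyclic
substrates, stereochemistry, or kinetic plausibility — so green tests
demonstrate correctness of the representation and algorithms, not
coverage of real-world chemical space.

Problem sizes used throughout the test and acceptance suites: 21 steps
(7 classes x 3 variants) for pipeline properties, 100 random
relabelings for the canonicalization convention, and a ~200-record index
(29 variants per class, deduplicated) for search-oracle agreement.

## Curation pipeline

Validation runs the three criteria in order — molecule parsing, label
and arrow-label consistency, step-object construction (including the
declared-versus-derived product cross-check) — and collects all
detectable failures instead of failing fast. A mismatch between
declared and derived products is reported under the step-object
criterion. Accepted submissions are flagged `pending_review`: the
plausibility stage of a hosted database is a human judgment (roughly,
whether the step proceeds on relevant timescales at room temperature)
and is modeled as a status, not an algorithm.

## Known limitations

* Aromatic systems are kekulized on input; arrow codes over aromatic
  bonds operate on the kekulé structure chosen by RDKit.
* Alpha-resonance chains through multiple lone pairs are rejected.
* The duplication check compares spectators as a multiset; a database
  that compares them as a set would merge records this package keeps
  distinct.
* Elements outside the H/C/N/O/halogen octet world (hypervalent S, P)
  are rejected by the electron-capacity check.
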
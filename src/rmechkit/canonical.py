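"""Canonical form of an elementary step.

Whatever integers a contributor used to label the participating atoms,
the stored record follows one convention:

* participating atoms of the *nucleophilic* component (the one donating
  the source MO's electron) are relabeled 10, 11, ... in mechanistic
  role order;
* participating atoms of the *electrophilic* component are relabeled
  20, 21, ...;
* molecule SMILES are canonicalized and dot-joined in sorted order;
* the arrow code is rewritten over the new labels and ordered so it
  begins from label 10.

Symmetric steps (homolysis, recombination of identical radicals) break
the nucleophile tie by canonical fragment SMILES, then canonical atom
rank; since ties only occur between graph-equivalent atoms, the emitted
record is independent of the choice.
"""

from __future__ import annotations

import hashlib

from rdkit import Chem

from . import mol as M
from .arrows import Arrow, AtomSite, BondSite, Site, format_arrows
from .classify import classify_mechanism, classify_phase
from .errors import StepObjectError
from .steps import (
    SHAPE_CHAIN,
    ElementaryStep,
    StepAnalysis,
    apply_step,
)

__all__ = ["canonicalize_step", "canonical_labeling"]


def canonical_labeling(step: ElementaryStep) -> dict[int, int]:
    """Map original participating labels -> conventional labels.

    Nucleophilic-component atoms take 10, 11, ...; electrophilic-component
    atoms take 20, 21, ...  Role order within each group follows the
    electron flow (see module docstring).
    """
    ana = step.analysis
    path = list(ana.path)
    if ana.shape == SHAPE_CHAIN:
        if ana.s1_order == 1:
            # sigma donor is the nucleophile: its atoms 10..., somo atom 20
            nucleo = list(reversed(path[1:]))
            electro = [path[0]]
        else:
            nucleo = [path[0]]
            electro = path[1:]
    else:
        # two-atom shapes: nucleophile-first pair
        nucleo, electro = [path[0]], [path[1]]
    mapping = {}
    for offset, label in enumerate(nucleo):
        mapping[label] = 10 + offset
    for offset, label in enumerate(electro):
        mapping[label] = 20 + offset
    # a chain may touch more atoms than the role lists (never for the
    # seven base categories); keep any stragglers deterministic
    extra = [l for l in sorted(step.participating_labels) if l not in mapping]
    next_label = max(mapping.values(), default=9) + 1
    for label in extra:  # pragma: no cover - defensive
        mapping[label] = next_label
        next_label += 1
    return mapping


def _relabel_site(site: Site, mapping: dict[int, int]) -> Site:
    if isinstance(site, AtomSite):
        return AtomSite(mapping[site.label])
    return BondSite(mapping[site.label1], mapping[site.label2])


def _canonical_arrows(arrows, mapping) -> list[Arrow]:
    new = [
        Arrow(_relabel_site(a.source, mapping), _relabel_site(a.target, mapping))
        for a in arrows
    ]
    return sorted(new, key=lambda a: (a.source.labels, a.target.labels))


def _relabel_mol(combined: Chem.Mol, mapping: dict[int, int]) -> Chem.Mol:
    out = Chem.Mol(combined)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(mapping.get(atom.GetAtomMapNum(), 0))
    return out


def _reactive_atom_smiles(combined: Chem.Mol, label: int) -> str:
    """SMILES of the molecule containing the reactive atom, that atom
    labeled 1 and all other labels cleared."""
    for frag in M.split(combined):
        labels = M.labels_of(frag)
        if label in labels:
            work = Chem.Mol(frag)
            for atom in work.GetAtoms():
                atom.SetAtomMapNum(1 if atom.GetAtomMapNum() == label else 0)
            return M.canonical_smiles(work)
    raise StepObjectError(f"reactive atom label {label} not found")  # pragma: no cover


def canonicalize_step(
    step: ElementaryStep,
    *,
    reaction_id: str | None = None,
    step_type: str = "core",
    condition: str = "",
    source: str = "",
):
    """Produce the canonical :class:`~rmechkit.records.ReactionRecord`.

    Original user labels are discarded; the record is invariant under
    relabeling of participating atoms, reordering of molecules and
    alternative SMILES spellings of the same structures.
    """
    from .records import ReactionRecord

    mechanism = classify_mechanism(step)
    phase = classify_phase(step)
    mapping = canonical_labeling(step)

    relabeled = _relabel_mol(step.combined, mapping)
    arrows = _canonical_arrows(step.arrows, mapping)
    reactants_smiles = M.molecules_string([relabeled])

    # translate the already-validated edits into the new label space and
    # re-apply them on the relabeled graph
    ana = step.analysis
    relabeled_analysis = StepAnalysis(
        shape=ana.shape,
        path=tuple(mapping[l] for l in ana.path),
        bond_deltas={_relabel_site(s, mapping): d for s, d in ana.bond_deltas.items()},
        radical_deltas={mapping[l]: d for l, d in ana.radical_deltas.items()},
        charge_deltas={mapping[l]: d for l, d in ana.charge_deltas.items()},
        p1_new=ana.p1_new,
        s1_order=ana.s1_order,
    )
    shadow = ElementaryStep(
        reactants=[relabeled],
        arrows=arrows,
        spectators=step.spectators,
        reactive_mo_source=step.reactive_mo_source,
        reactive_mo_sink=step.reactive_mo_sink,
        reactive_atom_1=mapping[step.reactive_atom_1],
        reactive_atom_2=mapping[step.reactive_atom_2],
        combined=relabeled,
        analysis=relabeled_analysis,
    )
    products = apply_step(shadow)
    products_smiles = M.molecules_string(products)
    spectators_smiles = M.molecules_string(step.spectators, keep_maps=False) if step.spectators else ""
    arrow_code = format_arrows(arrows)

    key = (reactants_smiles, products_smiles, arrow_code, spectators_smiles)
    if reaction_id is None:
        digest = hashlib.sha256("\x1f".join(key).encode()).hexdigest()[:12]
        reaction_id = f"R{digest}"

    return ReactionRecord(
        reaction_id=reaction_id,
        reactants_smiles=reactants_smiles,
        products_smiles=products_smiles,
        arrow_code=arrow_code,
        spectators_smiles=spectators_smiles,
        reactive_atom_1_smiles=_reactive_atom_smiles(relabeled, mapping[step.reactive_atom_1]),
        reactive_atom_2_smiles=_reactive_atom_smiles(relabeled, mapping[step.reactive_atom_2]),
        step_type=step_type,  # type: ignore[arg-type]
        condition=condition,  # type: ignore[arg-type]
        class_phase=phase,  # type: ignore[arg-type]
        class_mechanism=mechanism,  # type: ignore[arg-type]
        source=source,
    )
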
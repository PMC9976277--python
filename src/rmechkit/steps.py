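"""Elementary-step construction and product derivation.

A radical elementary step moves one electron between exactly two
reactive molecular orbitals (and therefore involves exactly two reactive
atoms, the main atoms of those MOs).  The arrows of the step's electron
flow specification are matched against the perceived MOs of the reactant
side; on success the step object records the source MO, the sink MO and
the unique electron-conserving set of bond/radical edits, from which the
products follow deterministically.

Arrow shapes recognized, by arrow count:

* 1 arrow  — alpha resonance: a lone pair adjacent to a somo.
* 2 arrows — bond homolysis (bond site feeding both of its atoms) or
  radical recombination (two somos feeding a new bond site).
* odd n >= 3 — an alternating chain ``a(r)>P1; S1>P1; S1>P2; ...;
  Sk>a(w)``: one radical (or bond-donor) terminus, ``k`` bonds gaining an
  order unit and ``k`` bonds losing one.  ``k = 1`` covers abstraction,
  addition, retro-addition and single-hop pi resonance; larger ``k``
  covers chained (long-range) resonance and conjugate addition.

Anything else cannot be explained by a single source/sink MO pair and
raises :class:`StepObjectError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from . import mol as M
from .arrows import Arrow, AtomSite, BondSite, Site
from .errors import (
    ApplyError,
    ArrowMismatchError,
    LabelError,
    StepObjectError,
    ValenceError,
)
from .orbitals import LONE_PAIR, PI, SIGMA, SOMO, MolecularOrbital

__all__ = ["ElementaryStep", "StepAnalysis", "build_step", "apply_step", "radical_delta"]

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}

# arrow-shape tags stored on the analysis; classify maps them (together
# with the MO kinds) onto the seven mechanism categories
SHAPE_HOMOLYSIS = "homolysis"
SHAPE_RECOMBINATION = "recombination"
SHAPE_CHAIN = "chain"
SHAPE_ALPHA = "alpha"


@dataclass
class StepAnalysis:
    """Structural signature extracted from the arrows.

    ``path`` lists participating atom labels in mechanistic role order:
    for the chain shape ``(r, x1, ..., x2k)`` following the arrows away
    from the donor/acceptor terminus ``r``; for the two-arrow shapes the
    (nucleophile-first) atom pair; for alpha resonance ``(lp_atom,
    somo_atom)``.
    """

    shape: str
    path: tuple[int, ...]
    bond_deltas: dict[BondSite, int]
    radical_deltas: dict[int, int]
    charge_deltas: dict[int, int] = field(default_factory=dict)
    p1_new: bool = False
    s1_order: int = 0


@dataclass
class ElementaryStep:
    """A validated elementary radical step (reactant side + arrows)."""

    reactants: list[Chem.Mol]
    arrows: list[Arrow]
    spectators: list[Chem.Mol]
    reactive_mo_source: MolecularOrbital
    reactive_mo_sink: MolecularOrbital
    reactive_atom_1: int  # label of the source MO's main atom
    reactive_atom_2: int  # label of the sink MO's main atom
    combined: Chem.Mol
    analysis: StepAnalysis
    products: Optional[list[Chem.Mol]] = None

    @property
    def label_to_index(self) -> dict[int, int]:
        return M.labels_of(self.combined)

    @property
    def participating_labels(self) -> frozenset[int]:
        out: set[int] = set()
        for arrow in self.arrows:
            out.update(arrow.labels)
        return frozenset(out)


def _check_distinct_labels(combined: Chem.Mol) -> dict[int, int]:
    seen: dict[int, int] = {}
    for atom in combined.GetAtoms():
        lab = atom.GetAtomMapNum()
        if lab <= 0:
            continue
        if lab in seen:
            raise LabelError(f"label {lab} used more than once", fragment=str(lab))
        seen[lab] = atom.GetIdx()
    return seen


def _site_labels(arrows: Sequence[Arrow]) -> set[int]:
    out: set[int] = set()
    for arrow in arrows:
        out.update(arrow.labels)
    return out


class _Ctx:
    """Label-space view of the combined reactant graph."""

    def __init__(self, combined: Chem.Mol, label2idx: dict[int, int]):
        self.mol = combined
        self.l2i = label2idx

    def atom(self, label: int) -> Chem.Atom:
        return self.mol.GetAtomWithIdx(self.l2i[label])

    def bond_order(self, site: BondSite) -> int:
        bond = self.mol.GetBondBetweenAtoms(self.l2i[site.label1], self.l2i[site.label2])
        return int(bond.GetBondTypeAsDouble()) if bond is not None else 0

    def radicals(self, label: int) -> int:
        return self.atom(label).GetNumRadicalElectrons()

    def lone_pairs(self, label: int) -> int:
        return M.lone_pairs(self.atom(label))

    def fragment_smiles(self, label: int) -> str:
        """Canonical unmapped SMILES of the component containing an atom."""
        frags = Chem.GetMolFrags(self.mol)
        idx = self.l2i[label]
        for atom_ids, frag in zip(frags, Chem.GetMolFrags(self.mol, asMols=True, sanitizeFrags=False)):
            if idx in atom_ids:
                return M.canonical_smiles(frag, keep_maps=False)
        raise KeyError(label)  # pragma: no cover


def build_step(
    reactants: Sequence[Chem.Mol],
    arrows: Sequence[Arrow],
    spectators: Sequence[Chem.Mol] = (),
) -> ElementaryStep:
    """Construct an :class:`ElementaryStep` from reactants and arrows.

    Identifies the unique (source MO, sink MO) pair consistent with all
    arrows and the electron-conserving edit set, or raises
    :class:`StepObjectError`.  Raises :class:`ArrowMismatchError` when an
    arrow references a label absent from the reactant side (including a
    participating hydrogen left implicit) and :class:`LabelError` on
    duplicate labels.
    """
    if not reactants:
        raise StepObjectError("no reactants")
    if not arrows:
        raise StepObjectError("no arrows")
    combined = M.combine(list(reactants))
    label2idx = _check_distinct_labels(combined)
    missing = sorted(_site_labels(arrows) - set(label2idx))
    if missing:
        raise ArrowMismatchError(
            f"arrow labels {missing} not present on the reactant side "
            "(a participating implicit hydrogen must be written explicitly and labeled)",
            fragment=",".join(map(str, missing)),
        )
    ctx = _Ctx(combined, label2idx)

    n = len(arrows)
    if n == 1:
        analysis, source, sink = _match_alpha(ctx, arrows[0])
    elif n == 2:
        analysis, source, sink = _match_two_arrows(ctx, arrows)
    elif n % 2 == 1:
        analysis, source, sink = _match_chain(ctx, arrows)
    else:
        raise StepObjectError(
            f"{n} arrows cannot be explained by a single source/sink MO pair"
        )

    step = ElementaryStep(
        reactants=list(reactants),
        arrows=list(arrows),
        spectators=list(spectators),
        reactive_mo_source=source,
        reactive_mo_sink=sink,
        reactive_atom_1=source.main_label,
        reactive_atom_2=sink.main_label,
        combined=combined,
        analysis=analysis,
    )
    # fail now, not at apply time, if the edits are chemically impossible
    apply_step(step)
    return step


def _mo_on_atom(ctx: _Ctx, kind: str, label: int, nascent: bool = False) -> MolecularOrbital:
    idx = ctx.l2i[label]
    return MolecularOrbital(kind, (idx,), idx, (label,), nascent=nascent)


def _mo_on_bond(ctx: _Ctx, kind: str, site: BondSite, main_label: int) -> MolecularOrbital:
    i, j = ctx.l2i[site.label1], ctx.l2i[site.label2]
    main = ctx.l2i[main_label]
    return MolecularOrbital(kind, (i, j), main, (site.label1, site.label2))


def _match_alpha(ctx: _Ctx, arrow: Arrow):
    """Single arrow: lone pair shifting toward an adjacent somo."""
    if not isinstance(arrow.source, AtomSite) or not isinstance(arrow.target, BondSite):
        raise StepObjectError(f"single arrow {arrow} is not a lone-pair shift")
    b_label = arrow.source.label
    if b_label not in arrow.target.labels:
        raise StepObjectError("lone-pair arrow must point at a bond of its own atom")
    a_label = next(l for l in arrow.target.labels if l != b_label)
    if ctx.bond_order(arrow.target) < 1:
        raise StepObjectError(f"no bond between atoms {arrow.target.label1} and {arrow.target.label2}")
    if ctx.lone_pairs(b_label) < 1:
        raise StepObjectError(f"atom {b_label} has no lone pair to donate")
    if ctx.radicals(a_label) < 1:
        raise StepObjectError(f"atom {a_label} carries no somo to accept the electron")
    analysis = StepAnalysis(
        shape=SHAPE_ALPHA,
        path=(b_label, a_label),
        bond_deltas={},
        radical_deltas={a_label: -1, b_label: +1},
        charge_deltas={a_label: -1, b_label: +1},
    )
    source = _mo_on_atom(ctx, LONE_PAIR, b_label)
    sink = _mo_on_atom(ctx, SOMO, a_label)
    return analysis, source, sink


def _match_two_arrows(ctx: _Ctx, arrows: Sequence[Arrow]):
    a1, a2 = arrows
    # homolysis shape: one bond site donating one electron to each atom
    if (
        isinstance(a1.source, BondSite)
        and a1.source == a2.source
        and {a1.target, a2.target} == {AtomSite(a1.source.label1), AtomSite(a1.source.label2)}
    ):
        site = a1.source
        order = ctx.bond_order(site)
        if order < 1:
            raise StepObjectError(f"no bond between atoms {site.label1} and {site.label2}")
        x, y = _homolysis_order(ctx, site)
        analysis = StepAnalysis(
            shape=SHAPE_HOMOLYSIS,
            path=(x, y),
            bond_deltas={site: -1},
            radical_deltas={x: +1, y: +1},
            s1_order=order,
        )
        kind = SIGMA if order == 1 else PI
        source = _mo_on_bond(ctx, kind, site, x)
        sink = _mo_on_atom(ctx, SOMO, y, nascent=True)
        return analysis, source, sink
    # recombination shape: two somos feeding the same nascent bond
    if (
        isinstance(a1.target, BondSite)
        and a1.target == a2.target
        and {a1.source, a2.source} == {AtomSite(a1.target.label1), AtomSite(a1.target.label2)}
    ):
        site = a1.target
        if ctx.bond_order(site) != 0:
            raise StepObjectError(
                f"atoms {site.label1} and {site.label2} are already bonded"
            )
        for lab in site.labels:
            if ctx.radicals(lab) < 1:
                raise StepObjectError(f"atom {lab} carries no somo")
        r1, r2 = _recombination_order(ctx, site)
        analysis = StepAnalysis(
            shape=SHAPE_RECOMBINATION,
            path=(r1, r2),
            bond_deltas={site: +1},
            radical_deltas={r1: -1, r2: -1},
        )
        source = _mo_on_atom(ctx, SOMO, r1)
        sink = _mo_on_atom(ctx, SOMO, r2)
        return analysis, source, sink
    raise StepObjectError("two arrows match neither homolysis nor recombination")


def _homolysis_order(ctx: _Ctx, site: BondSite) -> tuple[int, int]:
    """Order the two bond atoms nucleophile-first.

    The nascent fragment whose canonical SMILES sorts first is taken as
    nucleophilic; a ring bond (single fragment) falls back to canonical
    atom rank.
    """
    work = Chem.RWMol(ctx.mol)
    i, j = ctx.l2i[site.label1], ctx.l2i[site.label2]
    work.RemoveBond(i, j)
    work.GetAtomWithIdx(i).SetNumRadicalElectrons(
        work.GetAtomWithIdx(i).GetNumRadicalElectrons() + 1
    )
    work.GetAtomWithIdx(j).SetNumRadicalElectrons(
        work.GetAtomWithIdx(j).GetNumRadicalElectrons() + 1
    )
    frag_ids = Chem.GetMolFrags(work)
    frags = Chem.GetMolFrags(work, asMols=True, sanitizeFrags=False)
    smi = {}
    for atom_ids, frag in zip(frag_ids, frags):
        s = M.canonical_smiles(frag, keep_maps=False)
        for idx, lab in ((i, site.label1), (j, site.label2)):
            if idx in atom_ids:
                smi[lab] = s
    if smi.get(site.label1) == smi.get(site.label2):
        ranks = list(Chem.CanonicalRankAtoms(ctx.mol, breakTies=True))
        return (site.label1, site.label2) if ranks[i] <= ranks[j] else (site.label2, site.label1)
    if smi[site.label1] < smi[site.label2]:
        return site.label1, site.label2
    return site.label2, site.label1


def _recombination_order(ctx: _Ctx, site: BondSite) -> tuple[int, int]:
    """Nucleophile-first ordering of two recombining radicals: the one
    whose parent molecule's canonical SMILES sorts first."""
    s1 = ctx.fragment_smiles(site.label1)
    s2 = ctx.fragment_smiles(site.label2)
    if s1 == s2:
        return (site.label1, site.label2)
    return (site.label1, site.label2) if s1 < s2 else (site.label2, site.label1)


def _match_chain(ctx: _Ctx, arrows: Sequence[Arrow]):
    """Match an odd-length alternating chain of half arrows.

    ``a(r)>P1; S1>P1; S1>P2; S2>P2; ...; Sk>a(w)`` — bonds ``P_i`` gain
    one order unit (``P1`` may be nascent), bonds ``S_i`` lose one, the
    somo leaves ``r`` and appears on ``w``.  This is the resonance-chain
    generalization: lone pairs or pi bonds adjacent to pi-bond MOs chain
    into longer-range rearrangements.
    """
    atom_source = [a for a in arrows if isinstance(a.source, AtomSite)]
    atom_target = [a for a in arrows if isinstance(a.target, AtomSite)]
    if len(atom_source) != 1 or len(atom_target) != 1:
        raise StepObjectError(
            "a chain step needs exactly one atom-source and one atom-target arrow"
        )
    start, end = atom_source[0], atom_target[0]
    if not isinstance(start.target, BondSite) or not isinstance(end.source, BondSite):
        raise StepObjectError("chain terminus arrows must connect an atom to a bond")
    r = start.source.label
    if ctx.radicals(r) < 1:
        raise StepObjectError(f"atom {r} carries no somo to start the electron flow")
    if r not in start.target.labels:
        raise StepObjectError("first arrow must feed a bond at its own atom")

    by_source: dict[Site, list[Arrow]] = {}
    for a in arrows:
        by_source.setdefault(a.source, []).append(a)

    path = [r]
    consumed = {start}
    p_sites: list[BondSite] = [start.target]
    s_sites: list[BondSite] = []
    current_p = start.target
    prev_atom = r
    while True:
        next_atom = next(l for l in current_p.labels if l != prev_atom)
        path.append(next_atom)
        # the decreased bond S_i also targets current_p
        feeders = [
            a
            for a in arrows
            if a.target == current_p and a not in consumed and isinstance(a.source, BondSite)
        ]
        if len(feeders) != 1:
            raise StepObjectError(f"bond site {current_p} is not fed by exactly one bond arrow")
        s_arrow = feeders[0]
        s_site = s_arrow.source
        if next_atom not in s_site.labels:
            raise StepObjectError(f"chain breaks at atom {next_atom}")
        consumed.add(s_arrow)
        s_sites.append(s_site)
        far_atom = next(l for l in s_site.labels if l != next_atom)
        # the second arrow out of S_i: either the terminal atom arrow or
        # the next increased bond
        outgoing = [a for a in by_source.get(s_site, []) if a not in consumed]
        if len(outgoing) != 1:
            raise StepObjectError(f"bond site {s_site} must donate exactly two electrons")
        nxt = outgoing[0]
        consumed.add(nxt)
        if isinstance(nxt.target, AtomSite):
            if nxt is not end or nxt.target.label != far_atom:
                raise StepObjectError("chain must terminate on the far atom of its last bond")
            path.append(far_atom)
            break
        if far_atom not in nxt.target.labels:
            raise StepObjectError(f"chain breaks at atom {far_atom}")
        p_sites.append(nxt.target)
        prev_atom = far_atom
        current_p = nxt.target
    if consumed != set(arrows):
        raise StepObjectError("arrows do not form a single connected chain")

    # structural validation and edit assembly
    p1_order = ctx.bond_order(p_sites[0])
    p1_new = p1_order == 0
    for p in p_sites[1:]:
        if ctx.bond_order(p) < 1:
            raise StepObjectError(f"interior chain bond {p} does not exist")
    s1_order = ctx.bond_order(s_sites[0])
    for s in s_sites:
        if ctx.bond_order(s) < 1:
            raise StepObjectError(f"donating bond {s} does not exist")

    bond_deltas: dict[BondSite, int] = {}
    for p in p_sites:
        bond_deltas[p] = bond_deltas.get(p, 0) + 1
    for s in s_sites:
        bond_deltas[s] = bond_deltas.get(s, 0) - 1
    w = path[-1]
    analysis = StepAnalysis(
        shape=SHAPE_CHAIN,
        path=tuple(path),
        bond_deltas={k: v for k, v in bond_deltas.items() if v != 0},
        radical_deltas={r: -1, w: +1},
        p1_new=p1_new,
        s1_order=s1_order,
    )
    s1 = s_sites[0]
    # main-atom rule for the reacting bond MO: the atom gaining a new
    # bonding partner when P1 is nascent, otherwise the atom leaving with
    # (or toward) the relocated somo
    s1_main = path[1] if p1_new else path[2]
    if s1_order == 1:
        source = _mo_on_bond(ctx, SIGMA, s1, s1_main)
        sink = _mo_on_atom(ctx, SOMO, r)
    else:
        source = _mo_on_atom(ctx, SOMO, r)
        sink = _mo_on_bond(ctx, PI, s1, s1_main)
    return analysis, source, sink


def apply_step(step: ElementaryStep) -> list[Chem.Mol]:
    """Execute the step's bond edits and return the product molecules.

    Atom labels are preserved onto the products; spectators are passed
    through unchanged (and are not part of the return value).  Raises
    :class:`ApplyError` when an edit would exceed an atom's allowed
    valence or electron capacity.
    """
    if step.products is not None:
        return step.products
    work = Chem.RWMol(step.combined)
    for atom in work.GetAtoms():
        atom.SetNumExplicitHs(atom.GetTotalNumHs(includeNeighbors=False))
        atom.SetNoImplicit(True)
    l2i = M.labels_of(step.combined)

    ana = step.analysis
    for site, delta in ana.bond_deltas.items():
        i, j = l2i[site.label1], l2i[site.label2]
        bond = work.GetBondBetweenAtoms(i, j)
        order = int(bond.GetBondTypeAsDouble()) if bond is not None else 0
        new_order = order + delta
        if new_order < 0 or new_order > 3:
            raise ApplyError(f"bond {site} cannot reach order {new_order}")
        if bond is None:
            work.AddBond(i, j, _BOND_TYPES[new_order])
        elif new_order == 0:
            work.RemoveBond(i, j)
        else:
            bond.SetBondType(_BOND_TYPES[new_order])
    for label, delta in ana.radical_deltas.items():
        atom = work.GetAtomWithIdx(l2i[label])
        n = atom.GetNumRadicalElectrons() + delta
        if n < 0:
            raise ApplyError(f"atom {label} cannot lose a radical electron it does not have")
        atom.SetNumRadicalElectrons(n)
    for label, delta in ana.charge_deltas.items():
        atom = work.GetAtomWithIdx(l2i[label])
        atom.SetFormalCharge(atom.GetFormalCharge() + delta)

    out = work.GetMol()
    try:
        M.check_bookkeeping(out)
    except ValenceError as exc:
        raise ApplyError(str(exc), fragment=exc.fragment)
    # collapse frozen explicit-H bookkeeping back to the standard form
    products = [M.normalize(frag) for frag in M.split(out)]
    step.products = products
    return products


def radical_delta(step: ElementaryStep) -> int:
    """Total radical electrons in products minus reactants: +2 for
    homolysis, -2 for recombination, 0 for every other class."""
    return sum(step.analysis.radical_deltas.values())
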
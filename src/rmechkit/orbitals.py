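"""Molecular-orbital perception.

The elementary-step model treats a transition state as the movement of a
single electron between two reactive molecular orbitals.  Only four MO
kinds matter at this level of theory:

* ``somo`` — singly occupied MO, one per radical electron,
* ``sigma`` — one per unit bond, plus the sigma framework of every
  multiple bond,
* ``pi`` — one per unit of bond order above 1,
* ``lone_pair`` — one per nonbonded electron pair.

Each MO is associated with its *main atom* — for one-atom MOs the atom
itself, for bond MOs the partner chosen by the step context (the atom
that changes bonding partners) or, absent context, the lower canonical
rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .errors import ValenceError
from .mol import check_bookkeeping, lone_pairs

__all__ = ["MolecularOrbital", "perceive_orbitals"]

SOMO = "somo"
SIGMA = "sigma"
PI = "pi"
LONE_PAIR = "lone_pair"


@dataclass(frozen=True)
class MolecularOrbital:
    """One localized orbital.

    ``atoms`` holds atom indices (one for somo/lone_pair, two for
    sigma/pi) into the molecule the MO was perceived on; ``labels`` holds
    the corresponding atom-map numbers (0 for unlabeled atoms) so MOs can
    be compared in label space.  ``nascent`` marks an orbital that only
    exists on the product side (the new somo of a homolysis).
    """

    kind: str
    atoms: tuple[int, ...]
    main_atom: int
    labels: tuple[int, ...] = field(default=())
    nascent: bool = False

    def __post_init__(self) -> None:
        if self.main_atom not in self.atoms:
            raise ValueError("main_atom must belong to the MO's atom set")
        expected = 2 if self.kind in (SIGMA, PI) else 1
        if len(self.atoms) != expected:
            raise ValueError(f"{self.kind} MO needs {expected} atom(s)")

    @property
    def electron_occupancy(self) -> int:
        return 1 if self.kind == SOMO else 2

    @property
    def main_label(self) -> int:
        return self.labels[self.atoms.index(self.main_atom)] if self.labels else 0

    def key(self) -> tuple[str, frozenset[int]]:
        """Identity in label space, for cross-checking MO assignments."""
        return (self.kind, frozenset(self.labels))


def perceive_orbitals(mol: Chem.Mol, *, add_hs: bool = True) -> list[MolecularOrbital]:
    """Enumerate all localized MOs of a molecule.

    With ``add_hs`` (default) implicit hydrogens are made explicit first,
    so C-H sigma bonds appear as two-atom MOs; atom indices then refer to
    the explicit-H copy (original heavy-atom indices are preserved, Hs
    are appended).  Raises :class:`ValenceError` when electron
    bookkeeping is inconsistent for any atom.
    """
    check_bookkeeping(mol)
    work = Chem.AddHs(mol) if add_hs else Chem.Mol(mol)
    ranks = list(Chem.CanonicalRankAtoms(work, breakTies=True))
    label = {a.GetIdx(): a.GetAtomMapNum() for a in work.GetAtoms()}

    mos: list[MolecularOrbital] = []
    for atom in work.GetAtoms():
        idx = atom.GetIdx()
        for _ in range(atom.GetNumRadicalElectrons()):
            mos.append(MolecularOrbital(SOMO, (idx,), idx, (label[idx],)))
        n_lp = lone_pairs(atom)
        if n_lp < 0:
            raise ValenceError(f"negative lone-pair count on {atom.GetSymbol()}")
        for _ in range(n_lp):
            mos.append(MolecularOrbital(LONE_PAIR, (idx,), idx, (label[idx],)))
    for bond in work.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        main = i if ranks[i] <= ranks[j] else j
        order = int(bond.GetBondTypeAsDouble())
        mos.append(MolecularOrbital(SIGMA, (i, j), main, (label[i], label[j])))
        for _ in range(order - 1):
            mos.append(MolecularOrbital(PI, (i, j), main, (label[i], label[j])))
    return mos
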
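"""Mapped-molecule handling on top of RDKit.

Molecules are RDKit ``Mol`` objects throughout; atom labels are SMILES
atom-map numbers.  Two conventions matter everywhere:

* explicit hydrogens survive parsing (a participating H must be written
  explicitly and labeled), and
* canonical output removes explicit hydrogens *except labeled ones*, so
  ``Cl[H:11]`` stays distinct from ``Cl`` only while the H participates.

Radical electrons follow RDKit's valence-deficit convention; formal
charges and radical counts are cross-checked by :func:`check_bookkeeping`
against the element's valence-electron count.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

from .errors import ParseError, ValenceError

RDLogger.DisableLog("rdApp.*")

_PT = Chem.GetPeriodicTable()

_PARSER = Chem.SmilesParserParams()
_PARSER.removeHs = False

_REMOVE_H = Chem.RemoveHsParameters()
_REMOVE_H.removeMapped = False

# octet capacity in electrons: H holds at most 2, everything this package
# handles (C, N, O, halogens) at most 8
_CAPACITY = {1: 2}


def parse_smiles(text: str, *, allow_unmapped: bool = True) -> Chem.Mol:
    """Parse SMILES into a kekulized molecule, keeping explicit hydrogens.

    Raises :class:`ParseError` on syntax or valence failure.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty SMILES", fragment=text)
    mol = Chem.MolFromSmiles(text, _PARSER)
    if mol is None:
        raise ParseError(f"unparseable SMILES {text!r}", fragment=text)
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - rare
        raise ParseError(f"cannot kekulize {text!r}: {exc}", fragment=text)
    check_bookkeeping(mol, fragment=text)
    return mol


def check_bookkeeping(mol: Chem.Mol, fragment: str = "") -> None:
    """Verify per-atom electron bookkeeping.

    radicals + bonding electrons + lone-pair electrons must be consistent
    with the element's valence-electron count and formal charge, with a
    non-negative integer number of lone pairs and without exceeding the
    octet (duet for H).
    """
    if mol.GetNumAtoms() and mol.GetAtomWithIdx(0).GetImplicitValence() < 0:
        mol.UpdatePropertyCache(strict=False)
    for atom in mol.GetAtoms():
        if lone_pairs(atom) < 0:
            raise ValenceError(
                f"electron bookkeeping inconsistent for {atom.GetSymbol()} "
                f"(charge {atom.GetFormalCharge()}, {atom.GetNumRadicalElectrons()} "
                f"radical electrons, bond order sum {_bond_order_sum(atom)})",
                fragment=fragment or atom.GetSymbol(),
            )
        cap = _CAPACITY.get(atom.GetAtomicNum(), 8)
        if 2 * _bond_order_sum(atom) + nonbonding_electrons(atom) > cap:
            raise ValenceError(
                f"{atom.GetSymbol()} exceeds its electron capacity",
                fragment=fragment or atom.GetSymbol(),
            )


def _bond_order_sum(atom: Chem.Atom) -> int:
    total = atom.GetTotalNumHs(includeNeighbors=False)
    for bond in atom.GetBonds():
        total += int(bond.GetBondTypeAsDouble())
    return total


def nonbonding_electrons(atom: Chem.Atom) -> int:
    """Electrons on the atom not engaged in bonds (radicals + lone pairs)."""
    outer = _PT.GetNOuterElecs(atom.GetAtomicNum())
    return outer - atom.GetFormalCharge() - _bond_order_sum(atom)


def lone_pairs(atom: Chem.Atom) -> int:
    """Number of lone pairs; rounds down when bookkeeping leaves an odd
    electron that is not declared as a radical (rejected separately)."""
    nb = nonbonding_electrons(atom) - atom.GetNumRadicalElectrons()
    return nb // 2 if nb >= 0 else -1


def valence_electron_total(mol: Chem.Mol) -> int:
    """Total valence-electron count: 2 per bond order unit (incl. implicit
    H bonds), 2 per lone pair, 1 per radical electron."""
    total = 0
    for atom in mol.GetAtoms():
        total += 2 * lone_pairs(atom) + atom.GetNumRadicalElectrons()
        # each implicit H contributes one 2-electron sigma bond
        total += 2 * atom.GetTotalNumHs(includeNeighbors=False)
    for bond in mol.GetBonds():
        total += 2 * int(bond.GetBondTypeAsDouble())
    return total


def element_counts(mol: Chem.Mol) -> Counter:
    """Element multiset, counting implicit hydrogens."""
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs(includeNeighbors=False)
    return counts


def labels_of(mol: Chem.Mol) -> dict[int, int]:
    """Map of atom label -> atom index for labeled atoms."""
    return {
        a.GetAtomMapNum(): a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomMapNum() > 0
    }


def combine(mols: Sequence[Chem.Mol]) -> Chem.Mol:
    """Combine molecules into one (possibly disconnected) graph."""
    if not mols:
        raise ValueError("nothing to combine")
    out = mols[0]
    for m in mols[1:]:
        out = Chem.CombineMols(out, m)
    return out


def split(mol: Chem.Mol) -> list[Chem.Mol]:
    """Split into connected components (fragments)."""
    return list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False))


def canonical_smiles(mol: Chem.Mol, *, keep_maps: bool = True) -> str:
    """Canonical SMILES; explicit hydrogens folded in unless labeled."""
    work = Chem.Mol(mol)
    if not keep_maps:
        for atom in work.GetAtoms():
            atom.SetAtomMapNum(0)
    work = rdmolops.RemoveHs(work, _REMOVE_H)
    return Chem.MolToSmiles(work)


def canonical_fragment_smiles(
    mol: Chem.Mol, *, keep_maps: bool = True
) -> list[str]:
    """Sorted canonical SMILES of each connected component."""
    return sorted(canonical_smiles(f, keep_maps=keep_maps) for f in split(mol))


def molecules_string(mols: Iterable[Chem.Mol], *, keep_maps: bool = True) -> str:
    """Dot-joined sorted canonical SMILES of a molecule collection."""
    parts: list[str] = []
    for m in mols:
        parts.extend(canonical_fragment_smiles(m, keep_maps=keep_maps))
    return ".".join(sorted(parts))


def normalize(mol: Chem.Mol) -> Chem.Mol:
    """Round-trip a molecule through canonical SMILES.

    Collapses frozen explicit-H bookkeeping left behind by graph edits
    into the standard implicit-H representation.
    """
    return parse_smiles(canonical_smiles(mol))


def strip_maps(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out
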
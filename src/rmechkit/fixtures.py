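"""Deterministic fixture generator: valid steps for all seven mechanism
classes, plus invalid negatives for each validity criterion.

Templates use only H, C, O and halogens (charged species only in the
ketyl alpha-resonance template) so valence handling stays simple:

* homolysis — X-X (halogens) and O-O (peroxides),
* recombination — alkyl/halogen/oxy radical pairs,
* abstraction — H abstraction from alkanes by halogen / oxy radicals,
* addition — radical addition to terminal alkenes,
* retro-addition — beta-scission of alkyl / alkoxy radicals,
* pi resonance — allyl-type shifts,
* alpha resonance — ketyl radical anions.

Decoration replaces a hydrogen at a randomly chosen non-reacting
position with methyl, F or Cl under the seed, so arbitrarily many
distinct steps per class can be produced.  The same
:class:`FixtureSpec` always yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from rdkit import Chem

from . import mol as M
from .classify import MECHANISMS
from .errors import FixtureSpecError
from .io import parse_step
from .steps import apply_step

__all__ = ["FixtureSpec", "FixtureStep", "generate", "generate_invalid", "generate_suite"]


@dataclass(frozen=True)
class FixtureSpec:
    mechanism: str
    n: int = 1
    seed: int = 0
    decoration_depth: int = 0  # 0-3 substituent additions


@dataclass(frozen=True)
class FixtureStep:
    smirks: str  # reactants>>products, atom-mapped
    arrow_code: str
    mechanism: str
    condition: str = ""

    @property
    def reactants_smirks(self) -> str:
        return self.smirks.split(">>")[0]


# (reactants, arrow_code, condition); labels already follow the storage
# convention so the depth-0 first variants are the worked base cases
_TEMPLATES: dict[str, list[tuple[str, str, str]]] = {
    "homolysis": [
        ("[Cl:10][Cl:20]", "b10-20>a10;b10-20>a20", "light"),
        ("[Br:10][Br:20]", "b10-20>a10;b10-20>a20", "light"),
        ("[OH:10][OH:20]", "b10-20>a10;b10-20>a20", "heat"),
        ("C[O:10][O:20]C", "b10-20>a10;b10-20>a20", "heat"),
    ],
    "recombination": [
        ("[CH3:10].[CH3:20]", "a10>b10-20;a20>b10-20", ""),
        ("[CH3:10].[Cl:20]", "a10>b10-20;a20>b10-20", ""),
        ("C[CH2:10].[O:20]C", "a10>b10-20;a20>b10-20", ""),
    ],
    "abstraction": [
        ("[C:10]([H:11])([H])([H])[H].[Cl:20]", "b10-11>a10;b10-11>b11-20;a20>b11-20", ""),
        ("C[C:10]([H:11])([H])[H].[OH:20]", "b10-11>a10;b10-11>b11-20;a20>b11-20", ""),
        ("[C:10]([H:11])([H])([H])[H].[Br:20]", "b10-11>a10;b10-11>b11-20;a20>b11-20", ""),
    ],
    "addition": [
        ("[CH3:10].[CH2:20]=[CH2:21]", "a10>b10-20;b20-21>b10-20;b20-21>a21", ""),
        ("[OH:10].[CH2:20]=[CH2:21]", "a10>b10-20;b20-21>b10-20;b20-21>a21", ""),
        ("[Cl:10].[CH2:20]=[CH:21]C", "a10>b10-20;b20-21>b10-20;b20-21>a21", ""),
    ],
    "retro_addition": [
        ("[CH2:20][CH2:11][CH3:10]", "b10-11>a10;b10-11>b11-20;a20>b11-20", ""),
        ("[CH2:20][CH2:11][CH2:10]C", "b10-11>a10;b10-11>b11-20;a20>b11-20", ""),
        ("[O:20][CH2:11][CH3:10]", "b10-11>a10;b10-11>b11-20;a20>b11-20", "heat"),
    ],
    "pi_resonance": [
        ("[CH2:10][CH:20]=[CH2:21]", "a10>b10-20;b20-21>b10-20;b20-21>a21", ""),
        ("[CH2:10][C:20](C)=[CH2:21]", "a10>b10-20;b20-21>b10-20;b20-21>a21", ""),
        ("C[CH:10][CH:20]=[CH2:21]", "a10>b10-20;b20-21>b10-20;b20-21>a21", ""),
    ],
    "alpha_resonance": [
        ("[CH2:20][O-:10]", "a10>b10-20", ""),
        ("C[CH:20][O-:10]", "a10>b10-20", ""),
        ("C[C:20](C)[O-:10]", "a10>b10-20", ""),
    ],
}

_SUBSTITUENTS = ("C", "F", "Cl")


def _decorate_molecule(smiles: str, rng: random.Random) -> str:
    """Replace one H at a non-reacting position with a substituent.

    Labeled hydrogens (participating) are never touched; heavy atoms are
    eligible even when labeled as long as they keep a hydrogen to give.
    Returns the input unchanged when no position is eligible.
    """
    mol = Chem.RWMol(M.parse_smiles(smiles))
    candidates = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        if atom.GetTotalNumHs(includeNeighbors=False) > 0:
            candidates.append((atom.GetIdx(), None))
        else:
            for nbr in atom.GetNeighbors():
                if nbr.GetAtomicNum() == 1 and nbr.GetAtomMapNum() == 0:
                    candidates.append((atom.GetIdx(), nbr.GetIdx()))
                    break
    if not candidates:
        return smiles
    idx, h_idx = candidates[rng.randrange(len(candidates))]
    symbol = _SUBSTITUENTS[rng.randrange(len(_SUBSTITUENTS))]
    if h_idx is not None:
        mol.RemoveAtom(h_idx)
        if h_idx < idx:
            idx -= 1
    else:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetNumExplicitHs() > 0:
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    new_idx = mol.AddAtom(Chem.Atom(symbol))
    mol.AddBond(idx, new_idx, Chem.BondType.SINGLE)
    out = mol.GetMol()
    out.UpdatePropertyCache(strict=False)
    return M.canonical_smiles(out)


def _instantiate(reactants: str, arrow_code: str, rounds: int, rng: random.Random) -> str:
    parts = reactants.split(".")
    for _ in range(rounds):
        which = rng.randrange(len(parts))
        parts[which] = _decorate_molecule(parts[which], rng)
    return ".".join(parts)


def generate(spec: FixtureSpec) -> list[FixtureStep]:
    """Generate ``spec.n`` valid steps of one mechanism class.

    Every generated step passes validation and classifies to the
    expected class; identical specs yield byte-identical output.
    """
    if spec.mechanism not in _TEMPLATES:
        raise FixtureSpecError(f"unknown mechanism {spec.mechanism!r}", fragment=spec.mechanism)
    if spec.n < 1:
        raise FixtureSpecError("n must be >= 1")
    if not 0 <= spec.decoration_depth <= 3:
        raise FixtureSpecError("decoration depth must be in 0-3")
    variants = _TEMPLATES[spec.mechanism]
    out: list[FixtureStep] = []
    for i in range(spec.n):
        reactants, arrow_code, condition = variants[i % len(variants)]
        rounds = spec.decoration_depth + i // len(variants)
        rng = random.Random(f"{spec.seed}:{spec.mechanism}:{i}")
        decorated = _instantiate(reactants, arrow_code, rounds, rng)
        step = parse_step(decorated, arrow_code)
        products = M.molecules_string(apply_step(step))
        out.append(
            FixtureStep(
                smirks=f"{decorated}>>{products}",
                arrow_code=arrow_code,
                mechanism=spec.mechanism,
                condition=condition,
            )
        )
    return out


def generate_suite(n_per_class: int = 3, seed: int = 0, decoration_depth: int = 0) -> list[FixtureStep]:
    """One batch covering all seven mechanism classes."""
    out: list[FixtureStep] = []
    for mechanism in MECHANISMS:
        out.extend(generate(FixtureSpec(mechanism, n_per_class, seed, decoration_depth)))
    return out


_INVALID_KINDS = ("parse", "labels", "arrow_mismatch", "step_object")

_INVALID: dict[str, list[tuple[str, str, str]]] = {
    # (smirks, arrow_code, expected validity criterion)
    "parse": [
        ("C(C.[Cl:20]", "b10-20>a10;b10-20>a20", "parse"),
        ("[Cl:10][Cl:20]", "b10-20>a10;b10-20>", "parse"),
        ("[CH3:10].[CH3:20]>>C(C", "a10>b10-20;a20>b10-20", "parse"),
    ],
    "labels": [
        ("[C:10]([H:10])([H])([H])[H].[Cl:20]", "b10-11>a10;b10-11>b11-20;a20>b11-20", "labels"),
        ("[Cl:10][Cl:10]", "b10-20>a10;b10-20>a20", "labels"),
    ],
    "arrow_mismatch": [
        ("[Cl:10][Cl:20]", "b10-30>a10;b10-30>a30", "labels"),
        ("C.[Cl:20]", "b10-11>a10;b10-11>b11-20;a20>b11-20", "labels"),
    ],
    "step_object": [
        # saturated, radical-free: the recombination-shaped arrows have no somos
        ("[CH3:10][CH3:20]", "a10>b10-20;a20>b10-20", "step_object"),
        # two arrows between non-bonded atoms of different molecules
        ("[CH4:10].[Cl:20]Cl", "b10-20>a10;b10-20>a20", "step_object"),
        # declared products disagree with the arrows
        ("[Cl:10][Cl:20]>>ClCl", "b10-20>a10;b10-20>a20", "step_object"),
    ],
}


def generate_invalid(kind: str, seed: int = 0) -> tuple[str, str, str]:
    """An input failing validation on exactly the designated criterion.

    Returns (smirks, arrow_code, expected_criterion).
    """
    if kind not in _INVALID_KINDS:
        raise FixtureSpecError(f"unknown invalid kind {kind!r}", fragment=kind)
    variants = _INVALID[kind]
    return variants[random.Random(f"{seed}:{kind}").randrange(len(variants))]
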
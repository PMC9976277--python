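"""Parsing elementary steps from SMIRKS + arrow-code text.

A step is submitted as an atom-mapped SMIRKS (``reactants>>products``,
the product side optional) plus the arrow code.  Agents embedded in the
middle part of a three-part SMIRKS (``reactants>agents>products``) are
treated as spectators, as is anything passed through the separate
spectators field.
"""

from __future__ import annotations

from typing import Optional, Sequence

from rdkit import Chem

from . import mol as M
from .arrows import parse_arrow_code
from .errors import ParseError, ProductMismatchError
from .steps import ElementaryStep, apply_step, build_step

__all__ = ["parse_step", "split_smirks"]


def split_smirks(smirks: str) -> tuple[str, str, str]:
    """Split SMIRKS text into (reactants, agents, products) parts."""
    text = smirks.strip()
    if ">>" in text and text.count(">") == 2:
        reactants, products = text.split(">>")
        return reactants.strip(), "", products.strip()
    parts = text.split(">")
    if len(parts) == 1:
        return text, "", ""
    if len(parts) == 3:
        return parts[0].strip(), parts[1].strip(), parts[2].strip()
    raise ParseError(f"malformed SMIRKS {smirks!r}", fragment=smirks)


def _parse_molecules(text: str) -> list[Chem.Mol]:
    """Parse a dot-separated molecule list, one molecule per fragment."""
    mol = M.parse_smiles(text)
    return M.split(mol)


def _declared_products_match(step: ElementaryStep, declared: Sequence[Chem.Mol]) -> bool:
    derived = apply_step(step)
    keep_maps = any(M.labels_of(m) for m in declared)
    derived_s = sorted(
        s for m in derived for s in M.canonical_fragment_smiles(m, keep_maps=keep_maps)
    )
    declared_s = sorted(
        s for m in declared for s in M.canonical_fragment_smiles(m, keep_maps=keep_maps)
    )
    return derived_s == declared_s


def parse_step(
    smirks: str,
    arrow_code: str,
    spectators: str = "",
    *,
    check_products: bool = True,
) -> ElementaryStep:
    """Parse and orbital-check an elementary step.

    Delegates MO identification to :func:`~rmechkit.steps.build_step`.
    When the SMIRKS declares products they are cross-checked against the
    products derived from the arrows (:class:`ProductMismatchError` on
    disagreement) — by mapped canonical SMILES when the declared products
    carry atom maps, unmapped otherwise.
    """
    reactant_text, agent_text, product_text = split_smirks(smirks)
    if not reactant_text:
        raise ParseError("SMIRKS has no reactant side", fragment=smirks)
    reactants = _parse_molecules(reactant_text)

    spectator_mols: list[Chem.Mol] = []
    for text in (agent_text, spectators.strip()):
        if text:
            spectator_mols.extend(M.strip_maps(m) for m in _parse_molecules(text))

    declared: Optional[list[Chem.Mol]] = None
    if product_text:
        declared = _parse_molecules(product_text)

    arrows = parse_arrow_code(arrow_code)
    step = build_step(reactants, arrows, spectator_mols)

    if declared is not None and check_products:
        if not _declared_products_match(step, declared):
            raise ProductMismatchError(
                "declared products differ from the products derived from the arrows",
                fragment=product_text,
            )
    return step
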
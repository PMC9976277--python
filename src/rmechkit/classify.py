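"""Mechanism (7-class) and chain-phase (3-class) classification.

The seven mechanism categories are decided from the (source MO kind,
sink MO kind, bond-edit signature) of a built step:

==================  ======================================================
homolysis           sigma -> two nascent somos (2 arrows)
recombination       somo + somo -> new sigma (2 arrows)
abstraction         sigma -> somo, transferring an atom into a new bond
addition            somo + pi -> new sigma
retro_addition      sigma -> pi + somo (beta-scission)
pi_resonance        somo shifted through an adjacent pi system
alpha_resonance     somo + adjacent lone pair exchanged (1 arrow)
==================  ======================================================

The chain-phase label follows from the mechanism: homolysis initiates a
radical chain (+2 radicals), recombination terminates one (-2), and the
five remaining categories propagate it (radical count unchanged).
"""

from __future__ import annotations

from .errors import UnclassifiableError
from .orbitals import LONE_PAIR, PI, SIGMA, SOMO
from .steps import (
    SHAPE_ALPHA,
    SHAPE_CHAIN,
    SHAPE_HOMOLYSIS,
    SHAPE_RECOMBINATION,
    ElementaryStep,
)

__all__ = [
    "MECHANISMS",
    "PHASES",
    "PHASE_OF_MECHANISM",
    "classify_mechanism",
    "classify_phase",
]

HOMOLYSIS = "homolysis"
RECOMBINATION = "recombination"
ABSTRACTION = "abstraction"
ADDITION = "addition"
RETRO_ADDITION = "retro_addition"
ALPHA_RESONANCE = "alpha_resonance"
PI_RESONANCE = "pi_resonance"

INITIATION = "initiation"
PROPAGATION = "propagation"
TERMINATION = "termination"

MECHANISMS = (
    HOMOLYSIS,
    RECOMBINATION,
    ABSTRACTION,
    ADDITION,
    RETRO_ADDITION,
    ALPHA_RESONANCE,
    PI_RESONANCE,
)
PHASES = (INITIATION, PROPAGATION, TERMINATION)

PHASE_OF_MECHANISM = {
    HOMOLYSIS: INITIATION,
    RECOMBINATION: TERMINATION,
    ABSTRACTION: PROPAGATION,
    ADDITION: PROPAGATION,
    RETRO_ADDITION: PROPAGATION,
    ALPHA_RESONANCE: PROPAGATION,
    PI_RESONANCE: PROPAGATION,
}


def classify_mechanism(step: ElementaryStep) -> str:
    """Assign one of the seven mechanism categories to a built step.

    Raises :class:`UnclassifiableError` when the edit signature matches
    none of them (e.g. homolysis of a pi bond, which builds a valid
    electron-conserving diradical step but is no sigma homolysis).
    """
    ana = step.analysis
    src = step.reactive_mo_source.kind
    snk = step.reactive_mo_sink.kind
    if ana.shape == SHAPE_ALPHA and src == LONE_PAIR and snk == SOMO:
        return ALPHA_RESONANCE
    if ana.shape == SHAPE_HOMOLYSIS:
        if src == SIGMA and snk == SOMO:
            return HOMOLYSIS
        raise UnclassifiableError(
            f"{src} homolysis matches none of the seven categories"
        )
    if ana.shape == SHAPE_RECOMBINATION and src == SOMO and snk == SOMO:
        return RECOMBINATION
    if ana.shape == SHAPE_CHAIN:
        if ana.p1_new:
            # the somo terminus gains a brand-new bonding partner
            return ABSTRACTION if ana.s1_order == 1 else ADDITION
        return RETRO_ADDITION if ana.s1_order == 1 else PI_RESONANCE
    raise UnclassifiableError("edit signature matches none of the seven categories")


def classify_phase(step: ElementaryStep) -> str:
    """Chain-phase label: initiation, propagation or termination."""
    return PHASE_OF_MECHANISM[classify_mechanism(step)]
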
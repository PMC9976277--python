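"""Upload-style curation: validity check, duplication check, ingestion.

A submission passes through the same stages a hosted database applies to
community contributions:

1. **validity** — the SMILES must parse to valid molecular graphs, the
   participating atoms must be labeled with distinct integers consistent
   with the arrow codes, and the SMIRKS + arrows must yield an
   elementary step object (two reactive MOs / two reactive atoms);
2. **duplication** — two steps are equivalent iff their canonical
   reactant SMILES, product SMILES, spectator SMILES and conventional
   arrow code all agree;
3. **plausibility** — a manual curator stage, modeled here as the
   ``pending_review`` status flag on accepted records.

All detectable failures are collected per submission rather than failing
fast, so the report can carry an informative message for each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import mol as M
from .arrows import parse_arrow_code
from .canonical import canonicalize_step
from .errors import (
    ArrowMismatchError,
    LabelError,
    ParseError,
    ProductMismatchError,
    RMechError,
    StepObjectError,
)
from .io import parse_step, split_smirks
from .records import ReactionRecord
from .search import SearchIndex
from .steps import ElementaryStep, build_step

__all__ = [
    "Failure",
    "ValidationReport",
    "DuplicateVerdict",
    "IngestResult",
    "validate",
    "check_duplicate",
    "ingest",
]

# validity criteria, in checking order
CRITERION_PARSE = "parse"
CRITERION_LABELS = "labels"
CRITERION_STEP_OBJECT = "step_object"

_CRITERION_OF_CODE = {
    "E_PARSE": CRITERION_PARSE,
    "E_VALENCE": CRITERION_PARSE,
    "E_LABELS": CRITERION_LABELS,
    "E_ARROW_MISMATCH": CRITERION_LABELS,
    "E_STEP_OBJECT": CRITERION_STEP_OBJECT,
    "E_APPLY": CRITERION_STEP_OBJECT,
    "E_PRODUCT_MISMATCH": CRITERION_STEP_OBJECT,
}


@dataclass(frozen=True)
class Failure:
    criterion: str  # parse | labels | step_object
    message: str
    fragment: str = ""


@dataclass
class ValidationReport:
    failures: list[Failure] = field(default_factory=list)
    step: Optional[ElementaryStep] = None

    @property
    def status(self) -> str:
        return "valid" if not self.failures else "invalid"

    @property
    def is_valid(self) -> bool:
        return not self.failures


def _failure_from(exc: RMechError) -> Failure:
    criterion = _CRITERION_OF_CODE.get(exc.code, CRITERION_STEP_OBJECT)
    return Failure(criterion, exc.message, exc.fragment)


def validate(smirks: str, arrow_code: str, spectators: str = "") -> ValidationReport:
    """Run the three validity criteria in order, collecting all
    detectable failures; errors are the payload, never raised."""
    report = ValidationReport()

    # criterion 1: every molecule on both sides must parse
    try:
        reactant_text, agent_text, product_text = split_smirks(smirks)
    except ParseError as exc:
        report.failures.append(_failure_from(exc))
        return report
    parse_ok = True
    for side in (reactant_text, agent_text, product_text, spectators.strip()):
        if not side:
            continue
        for token in side.split("."):
            try:
                M.parse_smiles(token)
            except RMechError as exc:
                parse_ok = False
                report.failures.append(_failure_from(exc))
    if not reactant_text:
        parse_ok = False
        report.failures.append(
            Failure(CRITERION_PARSE, "SMIRKS has no reactant side", smirks)
        )
    try:
        arrows = parse_arrow_code(arrow_code)
    except ParseError as exc:
        parse_ok = False
        report.failures.append(_failure_from(exc))
    if not parse_ok:
        return report

    # criterion 2: distinct labels, arrows consistent with them
    try:
        reactants = M.split(M.parse_smiles(reactant_text))
        build_step(reactants, arrows)
    except (LabelError, ArrowMismatchError) as exc:
        report.failures.append(_failure_from(exc))
        return report
    except RMechError:
        pass  # step-object problems are criterion 3's business

    # criterion 3: the step object must be constructible (and declared
    # products, if any, must match the derived ones)
    try:
        report.step = parse_step(smirks, arrow_code, spectators)
    except (StepObjectError, ProductMismatchError, RMechError) as exc:
        report.failures.append(_failure_from(exc))
    return report


@dataclass(frozen=True)
class DuplicateVerdict:
    is_duplicate: bool
    matched_reaction_id: Optional[str]
    compared_components: tuple[str, str, str, str]


def check_duplicate(candidate: ElementaryStep, index: SearchIndex) -> DuplicateVerdict:
    """Duplicate iff an indexed record matches on all four canonical
    components (reactants, products, spectators, conventional arrows)."""
    record = canonicalize_step(candidate)
    match = index.lookup_key(record.key())
    return DuplicateVerdict(
        is_duplicate=match is not None,
        matched_reaction_id=match.reaction_id if match is not None else None,
        compared_components=record.key(),
    )


@dataclass
class Rejection:
    record: ReactionRecord
    reason: str  # invalid | duplicate
    report: Optional[ValidationReport] = None
    matched_reaction_id: Optional[str] = None


@dataclass
class IngestResult:
    accepted: list[ReactionRecord] = field(default_factory=list)
    rejected: list[Rejection] = field(default_factory=list)


def ingest(records: Iterable[ReactionRecord], index: SearchIndex) -> IngestResult:
    """Validate, canonicalize and deduplicate submissions into an index.

    Accepted records are re-canonicalized (user labels discarded, class
    labels recomputed), flagged ``pending_review`` to mirror the manual
    plausibility stage, and added to the index immediately — a duplicate
    later in the same batch is rejected.
    """
    result = IngestResult()
    for submitted in records:
        smirks = submitted.reactants_smiles
        if submitted.products_smiles:
            smirks = f"{smirks}>>{submitted.products_smiles}"
        report = validate(smirks, submitted.arrow_code, submitted.spectators_smiles)
        if not report.is_valid or report.step is None:
            result.rejected.append(Rejection(submitted, "invalid", report=report))
            continue
        verdict = check_duplicate(report.step, index)
        if verdict.is_duplicate:
            result.rejected.append(
                Rejection(
                    submitted,
                    "duplicate",
                    matched_reaction_id=verdict.matched_reaction_id,
                )
            )
            continue
        canonical = canonicalize_step(
            report.step,
            reaction_id=submitted.reaction_id or None,
            step_type=submitted.step_type,
            condition=submitted.condition,
            source=submitted.source,
        )
        canonical.status = "pending_review"
        index.add(canonical)
        result.accepted.append(canonical)
    return result
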
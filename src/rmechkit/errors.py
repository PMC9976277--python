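"""Exception hierarchy for elementary-step processing.

Every exception carries a short machine-readable ``code`` so that the
curation pipeline can collect failures by criterion instead of failing
fast.
"""

from __future__ import annotations


class RMechError(Exception):
    """Base class for all rmechkit errors."""

    code = "E_GENERIC"

    def __init__(self, message: str, fragment: str = "") -> None:
        super().__init__(message)
        #: the offending piece of input text, when identifiable
        self.fragment = fragment

    @property
    def message(self) -> str:
        return str(self)


class ParseError(RMechError):
    """SMILES/SMIRKS/arrow-code text could not be parsed."""

    code = "E_PARSE"


class LabelError(RMechError):
    """Atom labels on the reactant side are not distinct positive integers."""

    code = "E_LABELS"


class ArrowMismatchError(RMechError):
    """An arrow references a label absent from the reactant side."""

    code = "E_ARROW_MISMATCH"


class StepObjectError(RMechError):
    """No consistent pair of reactive MOs explains the arrows."""

    code = "E_STEP_OBJECT"


class ValenceError(RMechError):
    """Electron bookkeeping is inconsistent for an atom."""

    code = "E_VALENCE"


class ApplyError(RMechError):
    """Executing the bond edits would exceed an atom's allowed valence."""

    code = "E_APPLY"


class ProductMismatchError(RMechError):
    """Declared products differ from the products derived from the arrows."""

    code = "E_PRODUCT_MISMATCH"


class SchemaError(RMechError):
    """CSV header does not match the declared column set."""

    code = "E_SCHEMA"


class QueryLabelError(RMechError):
    """Reactive-atom query must contain exactly one atom labeled 1-9."""

    code = "E_QUERY_LABELS"


class UnclassifiableError(RMechError):
    """Step edits match none of the seven mechanism signatures."""

    code = "E_UNCLASSIFIABLE"


class FixtureSpecError(RMechError):
    """Invalid fixture-generation request."""

    code = "E_SPEC"
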
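"""The reaction record: schema, vocabulary and CSV (de)serialization.

A :class:`ReactionRecord` mirrors the download schema of an
elementary-step collection: canonical atom-mapped reactant SMILES,
canonical product SMILES, canonical arrow code, spectators, the two
reactive-atom SMILES (reactive atom labeled 1), step type, initial
condition, the two classification labels and a free-text source.

A record is uniquely keyed by its ``reaction_id`` and, alternatively, by
the combination (reactants, products, arrow code, spectators) — the four
components the duplication check compares.

CSV dialect: UTF-8, comma-delimited, quoted where needed, one header row
with the twelve column names in schema order.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, Field, ValidationError

from .errors import ParseError, SchemaError

__all__ = ["ReactionRecord", "CSV_COLUMNS", "read_csv", "write_csv", "CsvRecords"]

CSV_COLUMNS = (
    "reaction_id",
    "reactants_smiles",
    "products_smiles",
    "arrow_code",
    "spectators_smiles",
    "reactive_atom_1_smiles",
    "reactive_atom_2_smiles",
    "step_type",
    "condition",
    "class_phase",
    "class_mechanism",
    "source",
)

StepType = Literal["core", "specific"]
Condition = Literal["", "heat", "light"]  # blank = room temperature
Phase = Literal["initiation", "propagation", "termination"]
Mechanism = Literal[
    "homolysis",
    "recombination",
    "abstraction",
    "addition",
    "retro_addition",
    "alpha_resonance",
    "pi_resonance",
]


class ReactionRecord(BaseModel):
    """One elementary step plus its metadata, in canonical form."""

    reaction_id: str
    reactants_smiles: str
    products_smiles: str
    arrow_code: str
    spectators_smiles: str = ""
    reactive_atom_1_smiles: str = ""
    reactive_atom_2_smiles: str = ""
    step_type: StepType = "core"
    condition: Condition = ""
    class_phase: Optional[Phase] = None
    class_mechanism: Optional[Mechanism] = None
    source: str = ""
    #: curation status; accepted submissions await manual plausibility
    #: review.  Not part of the CSV schema.
    status: str = Field(default="pending_review", exclude=True)

    def key(self) -> tuple[str, str, str, str]:
        """The four canonical components of the duplication check."""
        return (
            self.reactants_smiles,
            self.products_smiles,
            self.arrow_code,
            self.spectators_smiles,
        )

    def to_row(self) -> list[str]:
        out = []
        for col in CSV_COLUMNS:
            val = getattr(self, col)
            out.append("" if val is None else str(val))
        return out

    @classmethod
    def from_row(cls, row: dict[str, str]) -> "ReactionRecord":
        data = {k: row.get(k, "") for k in CSV_COLUMNS}
        for optional in ("class_phase", "class_mechanism"):
            if data[optional] == "":
                data[optional] = None
        try:
            return cls(**data)
        except ValidationError as exc:
            first = exc.errors()[0]
            field = first.get("loc", ("?",))[0]
            raise ParseError(
                f"invalid value for column {field!r}: {first.get('msg')}",
                fragment=str(row.get(str(field), "")),
            )


class CsvRecords(list):
    """Records read from CSV; row-level failures are collected, not fatal."""

    def __init__(self, records: Iterable[ReactionRecord] = (), errors=None):
        super().__init__(records)
        #: list of (row_number, ParseError) for rows that failed validation
        self.errors: list[tuple[int, ParseError]] = list(errors or [])


def read_csv(path) -> CsvRecords:
    """Read reaction records from a CSV file.

    Raises :class:`SchemaError` when the header does not match the
    declared column set; invalid rows are collected on the returned
    list's ``errors`` attribute.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames
        if header is None:
            raise SchemaError("empty CSV file", fragment=str(path))
        missing = [c for c in CSV_COLUMNS if c not in header]
        unknown = [c for c in header if c not in CSV_COLUMNS]
        if missing or unknown:
            raise SchemaError(
                f"CSV header mismatch: missing {missing}, unknown {unknown}",
                fragment=",".join(header),
            )
        out = CsvRecords()
        for i, row in enumerate(reader, start=2):
            try:
                out.append(ReactionRecord.from_row(row))
            except ParseError as exc:
                out.errors.append((i, exc))
        return out


def write_csv(records: Iterable[ReactionRecord], path) -> None:
    """Write records to CSV (lossless round trip with :func:`read_csv`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for record in records:
            writer.writerow(record.to_row())
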
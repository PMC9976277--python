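"""Local searchable index over canonical reaction records.

Replicates the query semantics of a hosted step database: exact search
(containment of reactants and products, extra reagents allowed), search
by reactants/products, ECFP similarity search (Tanimoto / Dice / cosine
on binary circular fingerprints), molecule search, SMARTS substructure
search, reactive-atom search and metadata filters.

The index is a plain in-memory object rebuilt from CSV on demand; an
incremental build and a rebuild from the same records are identical.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import mol as M
from .errors import ParseError, QueryLabelError
from .io import split_smirks
from .records import ReactionRecord, read_csv

__all__ = ["SearchIndex", "SIMILARITY_METRICS", "similarity", "reaction_fingerprint", "filter_results"]

SIMILARITY_METRICS = ("tanimoto", "dice", "cosine")

REACTANT = "reactant"
PRODUCT = "product"
SPECTATOR = "spectator"


def similarity(a: np.ndarray, b: np.ndarray, metric: str = "tanimoto") -> float:
    """Similarity between two binary fingerprints, in [0, 1].

    With set-bit counts ``na``, ``nb`` and overlap ``c``: Tanimoto is
    ``c/(na+nb-c)``, Dice ``2c/(na+nb)``, cosine ``c/sqrt(na*nb)``.
    Identical nonempty fingerprints score 1 under all three; a pair with
    an empty member scores 0.
    """
    if metric not in SIMILARITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    c = int(np.count_nonzero(a & b))
    if na == 0 or nb == 0:
        return 0.0
    if metric == "tanimoto":
        return c / (na + nb - c)
    if metric == "dice":
        return 2 * c / (na + nb)
    return c / float(np.sqrt(na * nb))


class _Fingerprinter:
    """Reaction ECFP: union of reactant-molecule circular fingerprints
    concatenated with the union of product-molecule fingerprints."""

    def __init__(self, radius: int = 2, n_bits: int = 2048):
        self.radius = radius
        self.n_bits = n_bits
        self._gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)

    def side(self, mols: Sequence[Chem.Mol]) -> np.ndarray:
        out = np.zeros(self.n_bits, dtype=bool)
        for m in mols:
            work = M.strip_maps(m)
            Chem.SanitizeMol(work)  # fragments from a split lack ring info
            fp = self._gen.GetFingerprintAsNumPy(work)
            out |= fp.astype(bool)
        return out

    def reaction(self, reactants: Sequence[Chem.Mol], products: Sequence[Chem.Mol]) -> np.ndarray:
        return np.concatenate([self.side(reactants), self.side(products)])


def reaction_fingerprint(
    reactants: Sequence[Chem.Mol],
    products: Sequence[Chem.Mol],
    *,
    radius: int = 2,
    n_bits: int = 2048,
) -> np.ndarray:
    return _Fingerprinter(radius, n_bits).reaction(reactants, products)


@dataclass
class _Entry:
    record: ReactionRecord
    reactant_counts: Counter
    product_counts: Counter
    spectator_counts: Counter
    reactant_mols: list
    product_mols: list
    fingerprint: np.ndarray


def _side_mols(smiles: str) -> list[Chem.Mol]:
    if not smiles:
        return []
    return M.split(M.parse_smiles(smiles))


def _counts(mols: Iterable[Chem.Mol]) -> Counter:
    return Counter(M.canonical_smiles(m, keep_maps=False) for m in mols)


class SearchIndex:
    """Queryable collection of canonical, deduplicated reaction records."""

    def __init__(self, *, fp_radius: int = 2, fp_bits: int = 2048):
        self._fp = _Fingerprinter(fp_radius, fp_bits)
        self._entries: dict[str, _Entry] = {}
        self._by_key: dict[tuple[str, str, str, str], str] = {}
        #: canonical molecule SMILES -> {(reaction_id, role)}
        self.molecule_table: dict[str, set[tuple[str, str]]] = {}

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[ReactionRecord], **kwargs) -> "SearchIndex":
        index = cls(**kwargs)
        for record in records:
            index.add(record)
        return index

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SearchIndex":
        return cls.from_records(read_csv(path), **kwargs)

    def add(self, record: ReactionRecord) -> None:
        if record.reaction_id in self._entries:
            raise ValueError(f"duplicate reaction_id {record.reaction_id!r}")
        if record.key() in self._by_key:
            raise ValueError("record with identical canonical components already indexed")
        reactant_mols = _side_mols(record.reactants_smiles)
        product_mols = _side_mols(record.products_smiles)
        spectator_mols = _side_mols(record.spectators_smiles)
        entry = _Entry(
            record=record,
            reactant_counts=_counts(reactant_mols),
            product_counts=_counts(product_mols),
            spectator_counts=_counts(spectator_mols),
            reactant_mols=reactant_mols,
            product_mols=product_mols,
            fingerprint=self._fp.reaction(reactant_mols, product_mols),
        )
        self._entries[record.reaction_id] = entry
        self._by_key[record.key()] = record.reaction_id
        for counts, role in (
            (entry.reactant_counts, REACTANT),
            (entry.product_counts, PRODUCT),
            (entry.spectator_counts, SPECTATOR),
        ):
            for smiles in counts:
                self.molecule_table.setdefault(smiles, set()).add((record.reaction_id, role))

    # -- bookkeeping ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self._entries

    @property
    def records(self) -> list[ReactionRecord]:
        return [self._entries[k].record for k in sorted(self._entries)]

    def get(self, reaction_id: str) -> Optional[ReactionRecord]:
        entry = self._entries.get(reaction_id)
        return entry.record if entry else None

    def lookup_key(self, key: tuple[str, str, str, str]) -> Optional[ReactionRecord]:
        rid = self._by_key.get(key)
        return self._entries[rid].record if rid is not None else None

    def _sorted_entries(self) -> list[_Entry]:
        return [self._entries[k] for k in sorted(self._entries)]

    # -- reaction search ----------------------------------------------
    def search_exact(self, query_smirks: str) -> list[ReactionRecord]:
        """Records whose reactant and product sets contain the query's
        (no arrow code needed); extra spectators/reagents allowed."""
        reactant_text, _, product_text = split_smirks(query_smirks)
        if not reactant_text:
            raise ParseError("exact search query needs a reactant side", fragment=query_smirks)
        want_r = _counts(_side_mols(reactant_text))
        want_p = _counts(_side_mols(product_text)) if product_text else Counter()
        return [
            e.record
            for e in self._sorted_entries()
            if want_r <= e.reactant_counts and want_p <= e.product_counts
        ]

    def search_by_reactants(self, molecules: str) -> list[ReactionRecord]:
        """Steps whose reactants contain every query molecule."""
        if not molecules.strip():
            raise ParseError("empty molecule query", fragment=molecules)
        want = _counts(_side_mols(molecules))
        return [e.record for e in self._sorted_entries() if want <= e.reactant_counts]

    def search_by_products(self, molecules: str) -> list[ReactionRecord]:
        """Steps whose products contain every query molecule."""
        if not molecules.strip():
            raise ParseError("empty molecule query", fragment=molecules)
        want = _counts(_side_mols(molecules))
        return [e.record for e in self._sorted_entries() if want <= e.product_counts]

    def search_similar(
        self, query_smirks: str, metric: str = "tanimoto", n: int = 10
    ) -> list[tuple[ReactionRecord, float]]:
        """Top-``n`` records by descending reaction-fingerprint
        similarity; ties broken by reaction_id."""
        if n < 1:
            raise ValueError("n must be >= 1")
        reactant_text, _, product_text = split_smirks(query_smirks)
        query_fp = self._fp.reaction(
            _side_mols(reactant_text),
            _side_mols(product_text) if product_text else [],
        )
        scored = [
            (similarity(query_fp, e.fingerprint, metric), e.record)
            for e in self._sorted_entries()
        ]
        scored.sort(key=lambda t: (-t[0], t[1].reaction_id))
        return [(record, score) for score, record in scored[:n]]

    # -- compound search ----------------------------------------------
    def search_molecule(self, smiles: str) -> list[ReactionRecord]:
        """Records containing the molecule on the reactant or product side."""
        want = M.canonical_smiles(M.parse_smiles(smiles), keep_maps=False)
        return [
            e.record
            for e in self._sorted_entries()
            if want in e.reactant_counts or want in e.product_counts
        ]

    def search_substructure(self, smarts: str) -> list[ReactionRecord]:
        """Records with any reactant- or product-side molecule matching
        the SMARTS pattern."""
        pattern = Chem.MolFromSmarts(smarts)
        if pattern is None:
            raise ParseError(f"unparseable SMARTS {smarts!r}", fragment=smarts)
        out = []
        for e in self._sorted_entries():
            mols = e.reactant_mols + e.product_mols
            if any(m.HasSubstructMatch(pattern) for m in mols):
                out.append(e.record)
        return out

    def search_reactive_atom(self, mapped_smiles: str) -> list[ReactionRecord]:
        """Records where the single labeled atom (label 1-9) of the query
        molecule acts as one of the two reactive atoms.

        Matching is by atom environment: the query molecule must equal
        the stored parent molecule and the labeled atom must sit at the
        same canonical position as the stored reactive atom.
        """
        mol = M.parse_smiles(mapped_smiles)
        labeled = [a for a in mol.GetAtoms() if a.GetAtomMapNum() > 0]
        if len(labeled) != 1 or not (1 <= labeled[0].GetAtomMapNum() <= 9):
            raise QueryLabelError(
                "reactive-atom query needs exactly one atom labeled 1-9",
                fragment=mapped_smiles,
            )
        labeled[0].SetAtomMapNum(1)
        want = M.canonical_smiles(mol)
        return [
            e.record
            for e in self._sorted_entries()
            if want in (e.record.reactive_atom_1_smiles, e.record.reactive_atom_2_smiles)
        ]


def filter_results(
    results: Sequence,
    step_type: Optional[str] = None,
    class_phase: Optional[str] = None,
    class_mechanism: Optional[str] = None,
    condition: Optional[str] = None,
) -> list:
    """Conjunction of the provided metadata filters; works on records or
    (record, score) pairs."""

    def record_of(item):
        return item[0] if isinstance(item, tuple) else item

    def keep(item) -> bool:
        r = record_of(item)
        if step_type is not None and r.step_type != step_type:
            return False
        if class_phase is not None and r.class_phase != class_phase:
            return False
        if class_mechanism is not None and r.class_mechanism != class_mechanism:
            return False
        if condition is not None and r.condition != condition:
            return False
        return True

    return [item for item in results if keep(item)]
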
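"""Search semantics against brute-force linear-scan oracles."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from rmechkit import SearchIndex, filter_results, parse_step, canonicalize_step
from rmechkit import mol as M
from rmechkit.errors import ParseError, QueryLabelError
from rmechkit.search import similarity


def _vec(bits, size=16):
    out = np.zeros(size, dtype=bool)
    out[list(bits)] = True
    return out


def test_metric_closed_forms():
    # |a|=4, |b|=6, overlap 2
    a = _vec(range(4))
    b = _vec(range(2, 8))
    assert similarity(a, b, "tanimoto") == pytest.approx(0.25)
    assert similarity(a, b, "dice") == pytest.approx(0.4)
    assert similarity(a, b, "cosine") == pytest.approx(0.4082, abs=5e-5)


def test_self_similarity_is_one():
    a = _vec([1, 5, 9])
    for metric in ("tanimoto", "dice", "cosine"):
        assert similarity(a, a, metric) == 1.0
        assert similarity(a, _vec([]), metric) == 0.0


@settings(derandomize=True, max_examples=200)
@given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)))
def test_tanimoto_le_dice_and_symmetry(xs, ys):
    a, b = _vec(xs), _vec(ys)
    for metric in ("tanimoto", "dice", "cosine"):
        s = similarity(a, b, metric)
        assert 0.0 <= s <= 1.0
        assert s == similarity(b, a, metric)
    assert similarity(a, b, "tanimoto") <= similarity(a, b, "dice")


def _side_counts(smiles):
    if not smiles:
        return Counter()
    return Counter(
        M.canonical_smiles(f, keep_maps=False)
        for f in M.split(M.parse_smiles(smiles))
    )


def test_exact_search_ignores_spectators(index21):
    """A stored step is found by a query equal to it minus its
    spectators, and extra record spectators never block a match."""
    spectated = canonicalize_step(
        parse_step("[F:10][F:20]", "b10-20>a10;b10-20>a20", spectators="O"),
    )
    index = SearchIndex.from_records(index21.records + [spectated])
    hits = index.search_exact("FF>>[F].[F]")
    assert [h.reaction_id for h in hits] == [spectated.reaction_id]


def test_exact_search_unknown_product_empty(index21):
    assert index21.search_exact("ClCl>>ClBr") == []


def test_search_by_reactants_matches_linear_scan(big_index):
    for query in ("[CH3]", "C=C", "ClCl", "[OH]"):
        want = _side_counts(query)
        expected = [
            r.reaction_id
            for r in big_index.records
            if want <= _side_counts(r.reactants_smiles)
        ]
        got = [r.reaction_id for r in big_index.search_by_reactants(query)]
        assert got == expected


def test_search_by_products_matches_linear_scan(big_index):
    for query in ("[CH3]", "C=C", "Cl[H]"):
        want = _side_counts(query)
        expected = [
            r.reaction_id
            for r in big_index.records
            if want <= _side_counts(r.products_smiles)
        ]
        got = [r.reaction_id for r in big_index.search_by_products(query)]
        assert got == expected


def test_two_molecule_query_is_intersection(big_index):
    one = set(r.reaction_id for r in big_index.search_by_reactants("C"))
    two = set(r.reaction_id for r in big_index.search_by_reactants("[Cl]"))
    both = set(r.reaction_id for r in big_index.search_by_reactants("C.[Cl]"))
    assert both == one & two


def test_empty_query_is_error_not_full_scan(big_index):
    with pytest.raises(ParseError):
        big_index.search_by_reactants("")


def test_similarity_self_query_first(index21):
    record = index21.records[0]
    hits = index21.search_similar(
        record.reactants_smiles + ">>" + record.products_smiles, "tanimoto", 3
    )
    assert hits[0][0].reaction_id == record.reaction_id
    assert hits[0][1] == pytest.approx(1.0)
    scores = [s for _, s in hits]
    assert scores == sorted(scores, reverse=True)


def test_similarity_n_larger_than_index(index21):
    hits = index21.search_similar("ClCl>>[Cl].[Cl]", "dice", 10_000)
    assert len(hits) == len(index21)


def test_substructure_matches_linear_scan(big_index):
    pattern = Chem.MolFromSmarts("[Cl]")
    expected = []
    for r in big_index.records:
        mols = [
            M.parse_smiles(s)
            for side in (r.reactants_smiles, r.products_smiles)
            for s in side.split(".")
            if s
        ]
        if any(m.HasSubstructMatch(pattern) for m in mols):
            expected.append(r.reaction_id)
    got = [r.reaction_id for r in big_index.search_substructure("[Cl]")]
    assert got == expected and got


def test_molecule_search_either_side(index21):
    hits = index21.search_molecule("[CH3]")
    for r in index21.records:
        sides = _side_counts(r.reactants_smiles) + _side_counts(r.products_smiles)
        assert (r.reaction_id in [h.reaction_id for h in hits]) == ("[CH3]" in sides)


def test_reactive_atom_search(index21):
    hits = index21.search_reactive_atom("C=C[CH2:1]")
    assert hits
    for hit in hits:
        assert hit.class_mechanism == "pi_resonance"
    # any label 1-9 means the same query
    assert [h.reaction_id for h in index21.search_reactive_atom("C=C[CH2:7]")] == [
        h.reaction_id for h in hits
    ]


def test_reactive_atom_query_label_errors(index21):
    with pytest.raises(QueryLabelError):
        index21.search_reactive_atom("C=C[CH2]")  # no label
    with pytest.raises(QueryLabelError):
        index21.search_reactive_atom("[CH2:1]=C[CH2:2]")  # two labels
    with pytest.raises(QueryLabelError):
        index21.search_reactive_atom("C=C[CH2:10]")  # out of range


def test_filters_conjunctive(index21):
    records = index21.records
    assert filter_results(records) == records
    initiation = filter_results(records, class_phase="initiation")
    assert initiation and all(r.class_mechanism == "homolysis" for r in initiation)
    contradictory = filter_results(
        records, class_phase="initiation", class_mechanism="recombination"
    )
    assert contradictory == []


def test_rebuild_equals_incremental(tmp_path, records21):
    from rmechkit import read_csv, write_csv

    incremental = SearchIndex()
    for record in records21:
        incremental.add(record)
    path = tmp_path / "index.csv"
    write_csv(incremental.records, path)
    rebuilt = SearchIndex.from_csv(path)
    assert [r.model_dump() for r in rebuilt.records] == [
        r.model_dump() for r in incremental.records
    ]
    assert rebuilt.molecule_table == incremental.molecule_table
    for a, b in zip(rebuilt.records, incremental.records):
        assert np.array_equal(
            rebuilt._entries[a.reaction_id].fingerprint,
            incremental._entries[b.reaction_id].fingerprint,
        )
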
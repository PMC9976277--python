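"""Parsing, canonical labeling convention, CSV round trips."""

import random
import re

import pytest
from rdkit import Chem

from rmechkit import (
    ReactionRecord,
    canonicalize_step,
    parse_step,
    read_csv,
    write_csv,
)
from rmechkit import mol as M
from rmechkit.errors import (
    LabelError,
    ParseError,
    ProductMismatchError,
    SchemaError,
)
from rmechkit.records import CSV_COLUMNS


def test_unbalanced_parenthesis_is_parse_error():
    with pytest.raises(ParseError):
        parse_step("C(C", "b10-20>a10;b10-20>a20")


def test_duplicate_label_rejected():
    with pytest.raises(LabelError):
        parse_step(
            "[C:10]([H:10])([H])([H])[H].[Cl:20]",
            "b10-11>a10;b10-11>b11-20;a20>b11-20",
        )


def test_declared_products_cross_checked():
    smirks = "[Cl:10][Cl:20]>>ClCl"  # homolysis cannot give back Cl2
    with pytest.raises(ProductMismatchError):
        parse_step(smirks, "b10-20>a10;b10-20>a20")
    # correct declaration passes, mapped or unmapped
    parse_step("[Cl:10][Cl:20]>>[Cl].[Cl]", "b10-20>a10;b10-20>a20")
    parse_step("[Cl:10][Cl:20]>>[Cl:10].[Cl:20]", "b10-20>a10;b10-20>a20")


def test_abstraction_derived_products():
    step = parse_step(
        "[C:10]([H:11])([H])([H])[H].[Cl:20]",
        "b10-11>a10;b10-11>b11-20;a20>b11-20",
    )
    record = canonicalize_step(step)
    assert sorted(record.products_smiles.split(".")) == sorted(
        ["[CH3:10]", "[H:11][Cl:20]"]
    )


def test_canonical_labels_start_at_10():
    # user labels {3, 4, 7} -> canonical {10, 11, 20}
    step = parse_step(
        "[C:3]([H:4])([H])([H])[H].[Cl:7]",
        "b3-4>a3;b3-4>b4-7;a7>b4-7",
    )
    record = canonicalize_step(step)
    labels = {
        int(m) for m in re.findall(r":(\d+)\]", record.reactants_smiles)
    }
    assert labels == {10, 11, 20}
    assert record.arrow_code.split(">")[0] in ("a10", "b10-11")
    assert record.arrow_code == "b10-11>a10;b10-11>b11-20;a20>b11-20"


def test_canonicalization_idempotent(records21):
    for record in records21:
        step = parse_step(
            record.reactants_smiles + ">>" + record.products_smiles,
            record.arrow_code,
            record.spectators_smiles,
        )
        again = canonicalize_step(step)
        assert again.key() == record.key()


def _relabel_text(reactants, arrow_code, rng):
    """Randomly relabel participating atoms and shuffle molecule order."""
    mol = M.parse_smiles(reactants)
    labels = sorted(M.labels_of(mol))
    fresh = rng.sample(range(1, 400), len(labels))
    mapping = dict(zip(labels, fresh))
    work = Chem.Mol(mol)
    for atom in work.GetAtoms():
        if atom.GetAtomMapNum() > 0:
            atom.SetAtomMapNum(mapping[atom.GetAtomMapNum()])
    frags = [
        Chem.MolToSmiles(f)
        for f in Chem.GetMolFrags(work, asMols=True, sanitizeFrags=False)
    ]
    rng.shuffle(frags)
    code = re.sub(r"\d+", lambda m: str(mapping[int(m.group())]), arrow_code)
    return ".".join(frags), code


def test_canonicalization_invariant_under_relabeling(suite21, records21):
    rng = random.Random(2024)
    for fx, record in zip(suite21, records21):
        for _ in range(3):
            text, code = _relabel_text(fx.reactants_smirks, fx.arrow_code, rng)
            other = canonicalize_step(parse_step(text, code))
            assert other.key() == record.key(), (fx.mechanism, text, code)


def test_electrophile_labels_start_at_20(records21):
    for record in records21:
        labels = sorted(
            int(m) for m in re.findall(r":(\d+)\]", record.reactants_smiles)
        )
        assert labels[0] == 10
        high = [l for l in labels if l >= 20]
        if high:
            assert high[0] == 20


def test_csv_round_trip(tmp_path, records21):
    path = tmp_path / "steps.csv"
    write_csv(records21, path)
    back = read_csv(path)
    assert not back.errors
    assert [r.model_dump() for r in back] == [r.model_dump() for r in records21]
    # bit-exact second write
    path2 = tmp_path / "steps2.csv"
    write_csv(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_csv_missing_column_is_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    cols = [c for c in CSV_COLUMNS if c != "arrow_code"]
    path.write_text(",".join(cols) + "\n")
    with pytest.raises(SchemaError):
        read_csv(path)


def test_csv_bad_condition_collected_not_fatal(tmp_path, records21):
    path = tmp_path / "steps.csv"
    write_csv(records21[:2], path)
    lines = path.read_text().splitlines()
    lines[1] = lines[1].replace(",light,", ",lukewarm,")
    path.write_text("\n".join(lines) + "\n")
    back = read_csv(path)
    assert len(back) == 1
    assert len(back.errors) == 1
    row, err = back.errors[0]
    assert row == 2 and err.code == "E_PARSE"


def test_agents_in_smirks_become_spectators():
    step = parse_step("[Cl:10][Cl:20]>O>", "b10-20>a10;b10-20>a20")
    record = canonicalize_step(step)
    assert record.spectators_smiles == "O"


def test_record_key_is_four_components(records21):
    record = records21[0]
    assert record.key() == (
        record.reactants_smiles,
        record.products_smiles,
        record.arrow_code,
        record.spectators_smiles,
    )
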
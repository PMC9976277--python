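"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest

from rmechkit import (
    SearchIndex,
    canonicalize_step,
    generate_suite,
    parse_step,
    perceive_orbitals,
)
from rmechkit.arrows import AtomSite, BondSite
from rmechkit.orbitals import LONE_PAIR, PI, SIGMA, SOMO, MolecularOrbital


@pytest.fixture(scope="session")
def suite21():
    """Seven mechanism classes x 3 variants, deterministic."""
    return generate_suite(3, seed=0)


@pytest.fixture(scope="session")
def steps21(suite21):
    return [parse_step(fx.smirks, fx.arrow_code) for fx in suite21]


@pytest.fixture(scope="session")
def records21(suite21, steps21):
    return [
        canonicalize_step(step, condition=fx.condition)
        for fx, step in zip(suite21, steps21)
    ]


@pytest.fixture(scope="session")
def index21(records21):
    return SearchIndex.from_records(records21)


@pytest.fixture(scope="session")
def big_suite():
    """A larger fixture batch (~200 records) for search-oracle checks."""
    return generate_suite(29, seed=11, decoration_depth=0)


@pytest.fixture(scope="session")
def big_index(big_suite):
    index = SearchIndex()
    for fx in big_suite:
        record = canonicalize_step(parse_step(fx.smirks, fx.arrow_code), condition=fx.condition)
        if record.key() not in {r.key() for r in index.records}:
            index.add(record)
    return index


# ---------------------------------------------------------------------------
# Independent MO-pair oracle: exhaustive enumeration over perceived-MO
# pairs, kept deliberately separate from the arrow-template matcher the
# implementation uses.
# ---------------------------------------------------------------------------


def _mo_site(mo: MolecularOrbital):
    if len(mo.labels) == 1:
        return AtomSite(mo.labels[0])
    return BondSite(*mo.labels)


def _candidate_mos(step):
    """Perceived MOs on fully labeled atoms, plus nascent somos at every
    arrow-target atom site; deduplicated by (kind, label set)."""
    seen = {}
    for mo in perceive_orbitals(step.combined, add_hs=False):
        if 0 in mo.labels:
            continue
        # a sigma framework under a pi system is not the reacting MO;
        # the higher-energy pi electrons move first
        if mo.kind == SIGMA:
            bond = step.combined.GetBondBetweenAtoms(*mo.atoms)
            if bond is not None and bond.GetBondTypeAsDouble() > 1:
                continue
        seen.setdefault(mo.key(), mo)
    for arrow in step.arrows:
        if isinstance(arrow.target, AtomSite):
            label = arrow.target.label
            nascent = MolecularOrbital(SOMO, (0,), 0, (label,), nascent=True)
            seen.setdefault(("nascent", label), nascent)
    return list(seen.values())


def _pair_consistent(step, mo_a, mo_b) -> bool:
    sites = {_mo_site(mo_a), _mo_site(mo_b)}
    atoms = set(mo_a.labels) | set(mo_b.labels)
    joining = {
        BondSite(x, y) for x in mo_a.labels for y in mo_b.labels if x != y
    }
    out: dict = {}
    inn: dict = {}
    for arrow in step.arrows:
        out[arrow.source] = out.get(arrow.source, 0) + 1
        inn[arrow.target] = inn.get(arrow.target, 0) + 1
    # site coverage
    for arrow in step.arrows:
        if arrow.source not in sites:
            return False
        if arrow.target not in sites and arrow.target not in joining:
            if not (isinstance(arrow.target, AtomSite) and arrow.target.label in atoms):
                return False
    # electron ledger per MO
    target_atoms = {
        a.target.label for a in step.arrows if isinstance(a.target, AtomSite)
    } | {l for a in step.arrows if isinstance(a.target, BondSite) for l in a.target.labels}
    for mo in (mo_a, mo_b):
        occ = 0 if mo.nascent else mo.electron_occupancy
        site = _mo_site(mo)
        occ2 = occ - out.get(site, 0) + inn.get(site, 0)
        if occ2 not in (0, 1, 2):
            return False
        if occ2 == 1 and mo.kind != SOMO:
            # a doubly occupied MO left with an odd electron is only
            # possible where the relocated somo can land
            if not all(l in target_atoms for l in mo.labels):
                return False
    # at least one MO must actually change
    if all(
        out.get(_mo_site(mo), 0) == 0 and inn.get(_mo_site(mo), 0) == 0
        for mo in (mo_a, mo_b)
    ):
        return False
    return True


def mo_pair_oracle(step):
    """All unordered perceived-MO pairs consistent with the arrows, as
    frozensets of (kind, labels) keys; somo-dominated lone-pair pairs
    (the lone pair sitting on an atom that carries a somo doing the same
    job) are removed."""
    candidates = _candidate_mos(step)
    valid = []
    for mo_a, mo_b in itertools.combinations(candidates, 2):
        if _pair_consistent(step, mo_a, mo_b):
            valid.append((mo_a, mo_b))
    somo_atoms = {
        mo.labels[0] for mo, _ in valid if mo.kind == SOMO and not mo.nascent
    } | {mo.labels[0] for _, mo in valid if mo.kind == SOMO and not mo.nascent}
    filtered = []
    for mo_a, mo_b in valid:
        if any(
            mo.kind == LONE_PAIR and mo.labels[0] in somo_atoms for mo in (mo_a, mo_b)
        ):
            continue
        filtered.append(frozenset((mo_a.key(), mo_b.key())))
    return set(filtered)
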
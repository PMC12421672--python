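"""Ring-system selection, structure/name filters and pattern construction."""

import pytest
from hypothesis import given, strategies as st
from rdkit import Chem

from molannotate.extraction import (
    NamedSmilesRecord,
    extract_cyclic_patterns,
    is_ring_system_molecule,
    passes_name_filters,
    passes_structure_filters,
    ring_pattern_from_molecule,
)
from molannotate.fixtures import EXPECTED_SURVIVOR_NAMES, extraction_fixture_table


def mol(smiles):
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    return m


class TestRingSystemTest:
    @pytest.mark.parametrize("smiles,expected", [
        ("c1ccccc1", True),                 # all atoms and bonds cyclic
        ("Cc1ccccc1", False),               # methyl carbon breaks the rule
        ("O=C1CCCCC1", True),               # exocyclic C=O to terminal oxygen
        ("S=C1CCCCC1", True),               # same for sulfur
        ("Oc1ccccc1", False),               # terminal O single-bonded
        ("C=C1CCCCC1", False),              # exocyclic double bond to carbon
        ("c1ccc(-c2ccccc2)cc1", False),     # non-ring bond between ring atoms
        ("C1CCC2(CC1)CCCC2", True),         # spiro systems qualify
    ])
    def test_membership(self, smiles, expected):
        assert is_ring_system_molecule(mol(smiles)) is expected

    def test_sulfoxide_ring_oxygen_is_a_keeper(self):
        # terminal O double-bonded to an in-ring sulfur counts as exocyclic keeper
        assert is_ring_system_molecule(mol("O=S1CCCC1")) is True


class TestStructureFilters:
    @pytest.mark.parametrize("smiles,reason", [
        ("[13CH2]1CC1", "isotope"),
        ("C1CC1.C1CC1", "mixture"),
        ("[CH]1CC1", "radical"),
        ("C1" + "C" * 100 + "1", "too_large"),   # 101 heavy atoms
    ])
    def test_rejections(self, smiles, reason):
        d = passes_structure_filters(mol(smiles))
        assert (d.passed, d.reason) == (False, reason)

    def test_hundred_heavy_atoms_is_the_boundary(self):
        d = passes_structure_filters(mol("C1" + "C" * 99 + "1"))
        assert d.passed and d.reason == "ok"

    def test_first_failing_rule_wins(self):
        # a two-fragment radical reports mixture, not radical
        d = passes_structure_filters(mol("[CH]1CC1.C1CC1"))
        assert d.reason == "mixture"


class TestNameFilters:
    @pytest.mark.parametrize("name,reason", [
        ("CID1234567", "name_cid_prefix"),
        ("phenyl", "name_yl_suffix"),
        ("1,2,3,4,5-pentasomething", "name_numbers"),
        ("", "unparseable"),
        ("   ", "unparseable"),
    ])
    def test_rejections(self, name, reason):
        d = passes_name_filters(name)
        assert (d.passed, d.reason) == (False, reason)

    @pytest.mark.parametrize("name", [
        "benzene",
        "1,2,3,4-tetrahydroquinazoline",  # exactly four digit runs
        "CId-mixed-case",                 # prefix check is case-sensitive
        "methYL-insidE",                  # suffix only fires at the end
    ])
    def test_acceptances(self, name):
        assert passes_name_filters(name).passed

    def test_prefix_checked_before_suffix(self):
        assert passes_name_filters("CIDyl").reason == "name_cid_prefix"

    @given(st.lists(st.integers(min_value=0, max_value=99), min_size=0, max_size=8))
    def test_numbers_are_maximal_digit_runs(self, runs):
        """A name of digit runs joined by commas fails iff there are > 4 runs."""
        name = "x" + ",".join(str(r) for r in runs) + "-ine"
        decision = passes_name_filters(name)
        assert decision.passed == (len(runs) <= 4)


class TestRingPattern:
    def test_xanthine_pattern_matches_caffeine(self):
        smarts = ring_pattern_from_molecule(mol("C1=NC2=C(N1)C(=O)NC(=O)N2"))
        assert mol("CN1C=NC2=C1C(=O)N(C(=O)N2C)C").HasSubstructMatch(
            Chem.MolFromSmarts(smarts))

    def test_benzene_pattern_tolerates_any_substitution(self):
        smarts = ring_pattern_from_molecule(mol("c1ccccc1"))
        q = Chem.MolFromSmarts(smarts)
        for target in ("Cc1ccccc1", "Oc1ccccc1", "c1ccc(cc1)C(F)(F)F"):
            assert mol(target).HasSubstructMatch(q)

    def test_exocyclic_oxygen_keeps_degree_constraint(self):
        smarts = ring_pattern_from_molecule(mol("O=C1CCCCC1"))
        q = Chem.MolFromSmarts(smarts)
        assert not mol("OC1CCCCC1").HasSubstructMatch(q)   # cyclohexanol
        assert mol("O=C1CCCC(C)C1").HasSubstructMatch(q)   # substituted ketone

    def test_precondition_violation_raises(self):
        with pytest.raises(ValueError, match="ring system"):
            ring_pattern_from_molecule(mol("Cc1ccccc1"))

    def test_self_match_covers_all_atoms(self):
        for smiles in ("c1ccccc1", "O=C1CCCCC1", "c1ncc2nc[nH]c2n1",
                       "C1CCC2(CC1)CCCC2", "c1cc[nH+]cc1"):
            m = mol(smiles)
            q = Chem.MolFromSmarts(ring_pattern_from_molecule(m))
            match = m.GetSubstructMatch(q)
            assert len(match) == m.GetNumAtoms(), smiles


class TestPipeline:
    def test_fixture_table_reasons_match_hand_derivation(self):
        table = extraction_fixture_table()
        _, log = extract_cyclic_patterns([r for r, _ in table])
        assert len(log) == len(table)
        for (record, expected), entry in zip(table, log):
            assert entry.reason == expected, record.name
            assert entry.source_line == record.source_line

    def test_survivors_and_dedup_name_tiebreak(self):
        table = extraction_fixture_table()
        coll, _ = extract_cyclic_patterns([r for r, _ in table])
        assert [p.name for p in coll] == EXPECTED_SURVIVOR_NAMES
        assert all(p.category == "cyclic" for p in coll)

    def test_empty_input(self):
        coll, log = extract_cyclic_patterns([])
        assert len(coll) == 0 and log == []

    def test_emitted_patterns_self_match_their_source(self):
        table = extraction_fixture_table()
        coll, log = extract_cyclic_patterns([r for r, _ in table])
        by_name = {r.name: r.smiles for r, reason in table if reason == "ok"}
        for p in coll:
            source = mol(by_name[p.name])
            match = source.GetSubstructMatch(Chem.MolFromSmarts(p.smarts))
            assert len(match) == source.GetNumAtoms(), p.name

    def test_idempotence_on_own_output(self):
        table = extraction_fixture_table()
        coll1, _ = extract_cyclic_patterns([r for r, _ in table])
        by_name = {r.name: r.smiles for r, reason in table if reason == "ok"}
        again = [
            NamedSmilesRecord(name=p.name, smiles=by_name[p.name], source_line=i)
            for i, p in enumerate(coll1)
        ]
        coll2, _ = extract_cyclic_patterns(again)
        assert {p.smarts for p in coll2} == {p.smarts for p in coll1}

    def test_pass_fail_partition_independent_of_rule_order(self):
        """Only reason codes depend on filter order, not the partition."""
        table = extraction_fixture_table()
        for record, expected in table:
            m = Chem.MolFromSmiles(record.smiles) if record.smiles else None
            checks = [
                passes_structure_filters(m).passed,
                m is not None and is_ring_system_molecule(m),
                passes_name_filters(record.name).passed,
            ]
            assert all(checks) == (expected == "ok"), record.name
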